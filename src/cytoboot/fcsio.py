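"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Only the subset of the standard the pipeline touches is implemented: list-mode
($MODE L) floating point data ($DATATYPE F or D), little- or big-endian, with
channel names carried in $PnS (falling back to $PnN). Integer data, escaped
delimiters inside keyword values, and supplemental TEXT segments are not
supported. Files written here are FCS 3.0, float32 little-endian, so a
write/read round trip is exact to single precision.
"""
from __future__ import annotations

import numpy as np

from .errors import FormatError

_HEADER_LEN = 58  # "FCS3.0" + 4 spaces + six 8-char offset fields
_DELIM = "/"


def write_fcs(path, names, data) -> None:
    """Write a cells x channels float matrix as an FCS 3.0 file."""
    arr = np.ascontiguousarray(np.asarray(data, dtype="<f4"))
    if arr.ndim != 2:
        raise FormatError("FCS data must be a 2-D events x channels matrix")
    n_tot, n_par = arr.shape
    if len(names) != n_par:
        raise FormatError("channel name count does not match data columns")

    kw: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
        # fixed-width placeholders so offsets can be patched without resizing
        ("$BEGINDATA", "%012d"),
        ("$ENDDATA", "%012d"),
    ]
    for i, name in enumerate(names, start=1):
        if _DELIM in name:
            raise FormatError(f"channel name {name!r} contains the delimiter {_DELIM!r}")
        kw += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", name),
            (f"$P{i}S", name),
            (f"$P{i}R", "262144"),
        ]

    def render(begin: int, end: int) -> bytes:
        parts = []
        for key, val in kw:
            if val == "%012d":
                val = "%012d" % (begin if key == "$BEGINDATA" else end)
            parts.append(key + _DELIM + val)
        return (_DELIM + _DELIM.join(parts) + _DELIM).encode("ascii")

    text = render(0, 0)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + arr.nbytes - 1
    text = render(data_start, data_end)  # same length: fixed-width fields

    header = b"FCS3.0    " + b"".join(
        b"%8d" % v for v in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(arr.tobytes())


def read_fcs(path):
    """Read an FCS 3.0/3.1 file; returns ``(channel_names, events_array)``."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < _HEADER_LEN or not buf[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FormatError(f"{path}: not an FCS 3.0/3.1 file")

    def _off(lo: int) -> int:
        field = buf[lo : lo + 8].strip()
        return int(field) if field else 0

    text_start, text_end = _off(10), _off(18)
    data_start, data_end = _off(26), _off(34)

    text = buf[text_start : text_end + 1].decode("latin-1")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FormatError(f"{path}: malformed TEXT segment")
    kw = {k.strip().upper(): v for k, v in zip(tokens[::2], tokens[1::2])}

    if kw.get("$MODE", "L") != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) FCS is supported")
    dtype_code = kw.get("$DATATYPE", "")
    if dtype_code not in ("F", "D"):
        raise FormatError(f"{path}: unsupported $DATATYPE {dtype_code!r} (need F or D)")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")
    itemsize = 4 if dtype_code == "F" else 8
    dtype = np.dtype(f"{endian}f{itemsize}")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    raw = buf[data_start : data_start + n_tot * n_par * itemsize]
    if len(raw) < n_tot * n_par * itemsize:
        raise FormatError(f"{path}: truncated DATA segment")
    arr = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N")
        if not name:
            raise FormatError(f"{path}: channel {i} has neither $PnS nor $PnN")
        names.append(name)
    return names, arr
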