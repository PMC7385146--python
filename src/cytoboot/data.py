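"""Study data model and I/O.

A :class:`CellTable` holds one sample's single-cell event matrix (cells x
markers) together with the marker panel, optional per-cell population labels,
and a scale flag saying whether intensities are raw ion counts or already
arcsinh-transformed. A :class:`Study` bundles the per-sample tables with
patient-level metadata (patient id, treatment arm, timepoint) and the ordered
list of timepoints, baseline first.

On-disk formats: per-sample CSV (header row = marker names, optional
``population`` column) or FCS 3.0/3.1, a samples manifest CSV
(sample_id, patient_id, arm, timepoint, path), and a YAML marker panel.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fcsio
from .errors import ConsistencyError, FormatError
from .panel import MarkerPanel

log = logging.getLogger(__name__)

RAW = "raw"
ARCSINH = "arcsinh"

LABEL_COLUMN = "population"
MANIFEST_COLUMNS = ("sample_id", "patient_id", "arm", "timepoint", "path")


@dataclass
class CellTable:
    """One sample's cells x markers matrix with marker roles and labels."""

    sample_id: str
    data: pd.DataFrame
    panel: MarkerPanel
    labels: pd.Series | None = None
    scale: str = ARCSINH

    def __post_init__(self):
        missing = [m for m in self.panel.markers if m not in self.data.columns]
        if missing:
            raise FormatError(
                f"sample {self.sample_id!r} is missing panel marker(s): "
                + ", ".join(missing)
            )
        # canonical column order regardless of on-disk order
        self.data = self.data.loc[:, list(self.panel.markers)].reset_index(drop=True)
        if len(self.data) < 1:
            raise FormatError(f"sample {self.sample_id!r} has no cells")
        if not np.isfinite(self.data.to_numpy()).all():
            raise FormatError(f"sample {self.sample_id!r} contains non-finite values")
        if self.scale not in (RAW, ARCSINH):
            raise FormatError(f"unknown scale flag {self.scale!r}")
        if self.labels is not None:
            self.labels = pd.Series(self.labels).astype(str).reset_index(drop=True)
            if len(self.labels) != len(self.data):
                raise FormatError(
                    f"sample {self.sample_id!r}: {len(self.labels)} labels for "
                    f"{len(self.data)} cells"
                )

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def phenotypic_values(self) -> np.ndarray:
        return self.data.loc[:, list(self.panel.phenotypic)].to_numpy()

    def functional_values(self) -> np.ndarray:
        return self.data.loc[:, list(self.panel.functional)].to_numpy()


@dataclass
class Study:
    """All samples of one longitudinal two-arm study."""

    samples: dict[str, CellTable]
    metadata: pd.DataFrame  # indexed by sample_id: patient_id, arm, timepoint
    panel: MarkerPanel
    timepoint_order: tuple[str, ...]
    population_compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        md = self.metadata
        if len(md) == 0:
            raise ConsistencyError("study has no samples")
        if set(md.index) != set(self.samples):
            raise ConsistencyError("metadata sample_ids do not match cell tables")
        dup = md.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            pairs = md.loc[dup, ["patient_id", "timepoint"]].itertuples(index=False)
            raise ConsistencyError(
                "duplicate (patient, timepoint) pairs: "
                + "; ".join(f"({p}, {t})" for p, t in pairs)
            )
        unknown = set(md["timepoint"]) - set(self.timepoint_order)
        if unknown:
            raise ConsistencyError(f"timepoints not in timepoint_order: {unknown}")
        for ct in self.samples.values():
            if ct.panel.markers != self.panel.markers:
                raise ConsistencyError(
                    f"sample {ct.sample_id!r} uses a different marker panel"
                )

    # ---- convenience lookups -------------------------------------------
    @property
    def baseline_timepoint(self) -> str:
        return self.timepoint_order[0]

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.metadata["arm"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)

    def sample_ids_at(self, timepoint: str) -> list[str]:
        md = self.metadata
        return list(md.index[md["timepoint"] == timepoint])

    def baseline_sample_of(self, patient_id: str) -> str | None:
        md = self.metadata
        hit = md.index[
            (md["patient_id"] == patient_id)
            & (md["timepoint"] == self.baseline_timepoint)
        ]
        return hit[0] if len(hit) else None

    def neutrophil_populations(self) -> set[str]:
        return {
            p for p, c in self.population_compartments.items() if c == "neutrophil"
        }


# ---------------------------------------------------------------------------
# per-sample I/O
# ---------------------------------------------------------------------------

def read_sample(path, panel: MarkerPanel, *, scale: str = ARCSINH) -> CellTable:
    """Read one sample (CSV or FCS) into a :class:`CellTable`.

    Unknown extra CSV columns are preserved as labels when named
    ``population`` and otherwise ignored; cells with any non-finite value are
    dropped with a logged count.
    """
    path = os.fspath(path)
    sample_id = os.path.splitext(os.path.basename(path))[0]
    if path.lower().endswith(".fcs"):
        names, arr = fcsio.read_fcs(path)
        df = pd.DataFrame(arr, columns=names)
    else:
        df = pd.read_csv(path)
    missing = [m for m in panel.markers if m not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing panel marker(s): " + ", ".join(missing)
        )
    labels = df[LABEL_COLUMN].astype(str) if LABEL_COLUMN in df.columns else None
    extra = set(df.columns) - set(panel.markers) - {LABEL_COLUMN}
    if extra:
        log.info("%s: ignoring %d non-panel column(s): %s", path, len(extra), sorted(extra))
    values = df.loc[:, list(panel.markers)].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(values.to_numpy()).all(axis=1)
    if not keep.all():
        log.warning("%s: dropped %d cell(s) with non-finite values", path, int((~keep).sum()))
        values = values.loc[keep]
        if labels is not None:
            labels = labels.loc[keep]
    return CellTable(sample_id, values, panel, labels=labels, scale=scale)


def write_sample(table: CellTable, path) -> None:
    """Write one sample as CSV (with a ``population`` column) or FCS."""
    path = os.fspath(path)
    if path.lower().endswith(".fcs"):
        # FCS carries no label column; labels live in the CSV representation
        fcsio.write_fcs(path, list(table.panel.markers), table.data.to_numpy())
        return
    out = table.data.copy()
    if table.labels is not None:
        out[LABEL_COLUMN] = table.labels.to_numpy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifest / study assembly
# ---------------------------------------------------------------------------

def write_manifest(rows: pd.DataFrame, path) -> None:
    rows.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def assemble_study(
    manifest_path,
    panel: MarkerPanel,
    *,
    timepoint_order: tuple[str, ...] | None = None,
    population_compartments: dict[str, str] | None = None,
    scale: str = ARCSINH,
) -> Study:
    """Build a :class:`Study` from a samples manifest CSV.

    Manifest schema: sample_id, patient_id, arm, timepoint, path (paths are
    resolved relative to the manifest's directory). When ``timepoint_order``
    is omitted it is taken as the order of first appearance in the manifest,
    which must start with the baseline timepoint.
    """
    manifest_path = os.fspath(manifest_path)
    manifest = pd.read_csv(manifest_path)
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise FormatError(f"manifest missing column(s): {sorted(missing_cols)}")
    if len(manifest) == 0:
        raise ConsistencyError("manifest lists no samples")
    base_dir = os.path.dirname(os.path.abspath(manifest_path))
    samples: dict[str, CellTable] = {}
    for row in manifest.itertuples(index=False):
        p = row.path
        if not os.path.isabs(p):
            p = os.path.join(base_dir, p)
        ct = read_sample(p, panel, scale=scale)
        ct.sample_id = str(row.sample_id)
        samples[ct.sample_id] = ct
    metadata = (
        manifest.assign(sample_id=manifest["sample_id"].astype(str))
        .set_index("sample_id")[["patient_id", "arm", "timepoint"]]
        .astype(str)
    )
    if timepoint_order is None:
        timepoint_order = tuple(pd.unique(metadata["timepoint"]))
    return Study(
        samples=samples,
        metadata=metadata,
        panel=panel,
        timepoint_order=tuple(timepoint_order),
        population_compartments=dict(population_compartments or {}),
    )


def write_study(study: Study, outdir, *, fcs: bool = False) -> str:
    """Write every sample plus the manifest and panel; returns manifest path."""
    os.makedirs(outdir, exist_ok=True)
    ext = "fcs" if fcs else "csv"
    rows = []
    for sid in study.sample_ids:
        fname = f"{sid}.{ext}"
        write_sample(study.samples[sid], os.path.join(outdir, fname))
        md = study.metadata.loc[sid]
        rows.append((sid, md["patient_id"], md["arm"], md["timepoint"], fname))
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest_path = os.path.join(outdir, "manifest.csv")
    write_manifest(manifest, manifest_path)
    study.panel.to_yaml(os.path.join(outdir, "panel.yaml"))
    return manifest_path
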