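"""Marker panel definition.

A mass-cytometry panel is an ordered list of markers, each with a role:
*phenotypic* markers (surface proteins defining cell identity) drive the
clustering and the atlas, while *functional* markers (phospho-proteins and
other intracellular readouts) carry the signaling features. The default panel
mirrors a 26 phenotypic + 11 functional perioperative immunology design.
"""
from __future__ import annotations

from dataclasses import dataclass

import yaml

from .errors import ConfigurationError

PHENOTYPIC = "phenotypic"
FUNCTIONAL = "functional"

_DEFAULT_PHENOTYPIC = (
    "CD45", "CD66", "CD3", "CD4", "CD8a", "CD19", "CD20", "CD11b", "CD11c",
    "CD14", "CD16", "CD56", "CD25", "CD27", "CD33", "CD38", "CD45RA", "CD61",
    "CD123", "CD127", "HLA-DR", "Tbet", "FoxP3", "TCRgd", "CD235ab", "cPARP",
)
_DEFAULT_FUNCTIONAL = (
    "pSTAT1", "pSTAT3", "pSTAT5", "pSTAT6", "pNFkB", "pMAPKAPK2", "pP38",
    "prpS6", "pERK", "pCREB", "IkBa",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker names split by role."""

    phenotypic: tuple[str, ...]
    functional: tuple[str, ...]

    def __post_init__(self):
        names = self.markers
        if len(set(names)) != len(names):
            raise ConfigurationError("panel marker names must be unique")
        if not self.phenotypic:
            raise ConfigurationError("panel needs at least one phenotypic marker")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.phenotypic) + tuple(self.functional)

    def role(self, name: str) -> str:
        if name in self.phenotypic:
            return PHENOTYPIC
        if name in self.functional:
            return FUNCTIONAL
        raise KeyError(name)

    def roles(self) -> dict[str, str]:
        out = {m: PHENOTYPIC for m in self.phenotypic}
        out.update({m: FUNCTIONAL for m in self.functional})
        return out

    # ---- serialization (marker name -> role mapping, order preserving) ----
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {m: self.role(m) for m in self.markers}, fh, sort_keys=False
            )

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict) or not mapping:
            raise ConfigurationError(f"panel file {path} is not a marker->role mapping")
        phen, func = [], []
        for name, role in mapping.items():
            if role == PHENOTYPIC:
                phen.append(str(name))
            elif role == FUNCTIONAL:
                func.append(str(name))
            else:
                raise ConfigurationError(f"unknown marker role {role!r} for {name!r}")
        return cls(tuple(phen), tuple(func))


def default_panel() -> MarkerPanel:
    """The default 26 phenotypic + 11 functional marker panel."""
    return MarkerPanel(_DEFAULT_PHENOTYPIC, _DEFAULT_FUNCTIONAL)
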