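"""Synthetic two-arm, multi-timepoint mass-cytometry study generator.

The generator emulates the structure of a perioperative immune-monitoring
trial: two treatment arms (a glucocorticoid-like treatment vs. placebo
control), serial sampling at a baseline draw plus five post-surgery
timepoints, and a panel of 26 phenotypic + 11 functional markers measured on
mixtures of phenotypically distinct innate and adaptive immune cell
populations (plus one neutrophil population, which downstream clustering
excludes). Marker intensities are drawn as independent Gaussians per
population on the arcsinh scale — the scale on which the pipeline operates —
and raw-scale values are recoverable through the inverse transform.

Two kinds of perturbation can be planted:

* a *surgery response*: per-population, per-functional-marker additive time
  profiles applied to BOTH arms at post-baseline timepoints, emulating the
  stereotypical signaling response to surgical trauma; and
* arm-specific :class:`EffectSpec` entries that multiply a population's
  mixture fraction and/or shift its functional-marker means only in the
  target arm at the listed post-baseline timepoints — the ground truth that
  the classifier, atlas, and trajectory stages are expected to recover.

Every cell keeps its generating population as a ground-truth label, standing
in for manual gating.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ARCSINH, CellTable, Study
from .errors import ConfigurationError
from .panel import MarkerPanel, default_panel

INNATE = "innate"
ADAPTIVE = "adaptive"
NEUTROPHIL = "neutrophil"

DEFAULT_TIMEPOINTS = ("baseline", "1h", "6h", "24h", "48h", "2wk")

# lineage-defining phenotypic markers set "high" per population; everything
# else sits at a common low level
_LOW, _HIGH = 0.3, 3.8
_PHENOTYPE_SPREAD = 0.35
_FUNCTIONAL_BASELINE = 0.8
_FUNCTIONAL_SPREAD = 0.4

_DEFAULT_LINEAGES: dict[str, tuple[str, tuple[str, ...], float]] = {
    # name: (compartment, high markers, base fraction)
    "Neutrophils": (NEUTROPHIL, ("CD45", "CD66", "CD11b", "CD16"), 0.20),
    "cMC": (INNATE, ("CD45", "CD33", "CD14", "CD11b", "CD11c", "HLA-DR"), 0.12),
    "ncMC": (INNATE, ("CD45", "CD33", "CD16", "CD11c", "HLA-DR"), 0.04),
    "mDC": (INNATE, ("CD45", "CD11c", "HLA-DR", "CD123"), 0.02),
    "NK": (INNATE, ("CD45", "CD56", "CD16", "CD38"), 0.08),
    "M-MDSC": (INNATE, ("CD45", "CD33", "CD14", "CD11b", "CD38"), 0.02),
    "CD4Tnaive": (ADAPTIVE, ("CD45", "CD3", "CD4", "CD45RA", "CD27", "CD127"), 0.14),
    "CD4Tmem": (ADAPTIVE, ("CD45", "CD3", "CD4", "CD27", "CD127"), 0.14),
    "CD8T": (ADAPTIVE, ("CD45", "CD3", "CD8a", "CD45RA"), 0.10),
    "Bcells": (ADAPTIVE, ("CD45", "CD19", "CD20", "HLA-DR", "CD27"), 0.09),
    "Treg": (ADAPTIVE, ("CD45", "CD3", "CD4", "CD25", "FoxP3"), 0.05),
}


@dataclass
class PopulationSpec:
    """Generating distribution of one cell population (arcsinh-scale units)."""

    name: str
    compartment: str  # innate | adaptive | neutrophil
    phenotype_centers: dict[str, float]
    phenotype_spread: dict[str, float]
    functional_baseline: dict[str, float]
    functional_spread: dict[str, float]
    base_fraction: float

    def validate(self, panel: MarkerPanel) -> None:
        if self.compartment not in (INNATE, ADAPTIVE, NEUTROPHIL):
            raise ConfigurationError(
                f"population {self.name!r}: unknown compartment {self.compartment!r}"
            )
        if not 0.0 <= self.base_fraction <= 1.0:
            raise ConfigurationError(
                f"population {self.name!r}: base_fraction outside [0, 1]"
            )
        for m in panel.phenotypic:
            if m not in self.phenotype_centers:
                raise ConfigurationError(f"population {self.name!r}: no center for {m!r}")
            if self.phenotype_spread.get(m, 0.0) <= 0:
                raise ConfigurationError(f"population {self.name!r}: spread for {m!r} must be > 0")
        for m in panel.functional:
            if m not in self.functional_baseline:
                raise ConfigurationError(f"population {self.name!r}: no baseline for {m!r}")
            if self.functional_spread.get(m, 0.0) <= 0:
                raise ConfigurationError(f"population {self.name!r}: spread for {m!r} must be > 0")


@dataclass
class EffectSpec:
    """Arm-specific perturbation planted at post-baseline timepoints."""

    population: str
    arm: str
    timepoints: tuple[str, ...]
    frequency_multiplier: float = 1.0
    signaling_shift: dict[str, float] = field(default_factory=dict)

    def validate(self, config: "StudyConfig") -> None:
        names = {p.name for p in config.populations}
        if self.population not in names:
            raise ConfigurationError(f"effect targets unknown population {self.population!r}")
        if self.arm not in config.arms:
            raise ConfigurationError(f"effect targets unknown arm {self.arm!r}")
        if self.frequency_multiplier <= 0:
            raise ConfigurationError("frequency_multiplier must be > 0")
        baseline = config.timepoints[0]
        for tp in self.timepoints:
            if tp == baseline:
                raise ConfigurationError("effects may not target the baseline timepoint")
            if tp not in config.timepoints:
                raise ConfigurationError(f"effect targets unknown timepoint {tp!r}")
        functional = set(config.panel.functional)
        unknown = set(self.signaling_shift) - functional
        if unknown:
            raise ConfigurationError(f"signaling_shift names non-functional marker(s): {sorted(unknown)}")


@dataclass
class StudyConfig:
    """Full description of one synthetic study; same seed => same study."""

    n_patients_per_arm: int | tuple[int, int] = (30, 28)
    arms: tuple[str, str] = ("control", "MP")
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    cells_per_sample: int | tuple[int, int] = (1500, 2500)
    panel: MarkerPanel = field(default_factory=default_panel)
    populations: list[PopulationSpec] = field(default_factory=list)
    effects: list[EffectSpec] = field(default_factory=list)
    # population -> functional marker -> timepoint -> additive shift (both arms)
    surgery_response: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not self.populations:
            self.populations = default_populations(self.panel)
        if not self.surgery_response:
            self.surgery_response = default_surgery_response()

    @property
    def arm_sizes(self) -> tuple[int, int]:
        n = self.n_patients_per_arm
        return (int(n), int(n)) if isinstance(n, (int, np.integer)) else (int(n[0]), int(n[1]))

    def validate(self) -> None:
        if len(self.timepoints) < 2:
            raise ConfigurationError("need at least two timepoints (baseline + one post)")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigurationError("timepoints must be unique")
        if len(self.arms) != 2 or self.arms[0] == self.arms[1]:
            raise ConfigurationError("need exactly two distinct arms")
        for n in self.arm_sizes:
            if n < 2:
                raise ConfigurationError("each arm needs at least 2 patients")
        cells = self.cells_per_sample
        if isinstance(cells, (int, np.integer)):
            if cells <= 0:
                raise ConfigurationError("cells_per_sample must be positive")
        else:
            lo, hi = cells
            if lo <= 0 or hi < lo:
                raise ConfigurationError("cells_per_sample range must be positive and ordered")
        total = sum(p.base_fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"population base_fractions sum to {total}, not 1")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("population names must be unique")
        for p in self.populations:
            p.validate(self.panel)
        for e in self.effects:
            e.validate(self)
        baseline = self.timepoints[0]
        for pop, per_marker in self.surgery_response.items():
            for marker, profile in per_marker.items():
                if marker not in self.panel.functional:
                    raise ConfigurationError(
                        f"surgery_response names non-functional marker {marker!r}"
                    )
                if baseline in profile:
                    raise ConfigurationError("surgery_response may not shift the baseline timepoint")

    def compartments(self) -> dict[str, str]:
        return {p.name: p.compartment for p in self.populations}


def default_populations(panel: MarkerPanel | None = None) -> list[PopulationSpec]:
    """Eleven populations spanning the neutrophil/innate/adaptive compartments."""
    panel = panel or default_panel()
    pops = []
    for name, (compartment, high, frac) in _DEFAULT_LINEAGES.items():
        centers = {m: (_HIGH if m in high else _LOW) for m in panel.phenotypic}
        pops.append(
            PopulationSpec(
                name=name,
                compartment=compartment,
                phenotype_centers=centers,
                phenotype_spread={m: _PHENOTYPE_SPREAD for m in panel.phenotypic},
                functional_baseline={m: _FUNCTIONAL_BASELINE for m in panel.functional},
                functional_spread={m: _FUNCTIONAL_SPREAD for m in panel.functional},
                base_fraction=frac,
            )
        )
    return pops


def default_surgery_response() -> dict[str, dict[str, dict[str, float]]]:
    """Both-arm post-surgery signaling activation, strongest early, gone by 2 wk.

    Innate populations mount prominent STAT3/CREB/MAPK responses; adaptive
    populations a milder STAT3/STAT5 response.
    """
    early = {"1h": 1.0, "6h": 0.8, "24h": 0.5, "48h": 0.25}
    mild = {"1h": 0.5, "6h": 0.4, "24h": 0.25, "48h": 0.1}
    return {
        "cMC": {"pSTAT3": dict(early), "pCREB": dict(early), "pMAPKAPK2": dict(mild)},
        "Neutrophils": {"pSTAT3": dict(early), "pP38": dict(mild)},
        "NK": {"pSTAT1": dict(mild)},
        "CD4Tmem": {"pSTAT3": dict(mild), "pSTAT5": dict(mild)},
        "CD4Tnaive": {"pSTAT5": dict(mild)},
        "CD8T": {"pSTAT3": dict(mild)},
    }


def treatment_like_effects(
    arm: str = "MP",
    timepoints: tuple[str, ...] = ("1h", "6h", "24h"),
) -> list[EffectSpec]:
    """A glucocorticoid-like planted ground truth for demos.

    Attenuated STAT3/STAT5 responses and reduced frequencies in CD4 T cell
    populations, elevated IkBa broadly, and increased NK frequency.
    """
    return [
        EffectSpec("CD4Tmem", arm, timepoints, frequency_multiplier=0.6,
                   signaling_shift={"pSTAT3": -0.8, "pSTAT5": -0.7, "IkBa": 0.6}),
        EffectSpec("CD4Tnaive", arm, timepoints, frequency_multiplier=0.7,
                   signaling_shift={"pSTAT3": -0.6, "pSTAT5": -0.6, "IkBa": 0.6}),
        EffectSpec("CD8T", arm, timepoints, signaling_shift={"pSTAT5": -0.5, "IkBa": 0.5}),
        EffectSpec("cMC", arm, timepoints, frequency_multiplier=0.8,
                   signaling_shift={"IkBa": 0.6}),
        EffectSpec("NK", arm, timepoints, frequency_multiplier=1.4),
    ]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_fractions(config: StudyConfig, arm: str, timepoint: str) -> np.ndarray:
    fracs = np.array([p.base_fraction for p in config.populations], dtype=float)
    for effect in config.effects:
        if effect.arm == arm and timepoint in effect.timepoints:
            idx = next(
                i for i, p in enumerate(config.populations) if p.name == effect.population
            )
            fracs[idx] *= effect.frequency_multiplier
    return fracs / fracs.sum()


def _functional_means(
    config: StudyConfig, pop: PopulationSpec, arm: str, timepoint: str
) -> np.ndarray:
    means = np.array(
        [pop.functional_baseline[m] for m in config.panel.functional], dtype=float
    )
    profile = config.surgery_response.get(pop.name, {})
    for j, marker in enumerate(config.panel.functional):
        means[j] += profile.get(marker, {}).get(timepoint, 0.0)
    for effect in config.effects:
        if (
            effect.population == pop.name
            and effect.arm == arm
            and timepoint in effect.timepoints
        ):
            for j, marker in enumerate(config.panel.functional):
                means[j] += effect.signaling_shift.get(marker, 0.0)
    return means


def generate_study(config: StudyConfig) -> Study:
    """Draw one full study; bit-identical for identical configs."""
    config.validate()
    panel = config.panel
    n_phen, n_func = len(panel.phenotypic), len(panel.functional)
    phen_centers = np.array(
        [[p.phenotype_centers[m] for m in panel.phenotypic] for p in config.populations]
    )
    phen_spread = np.array(
        [[p.phenotype_spread[m] for m in panel.phenotypic] for p in config.populations]
    )
    func_spread = np.array(
        [[p.functional_spread[m] for m in panel.functional] for p in config.populations]
    )

    plan = []  # (sample_id, patient_id, arm, timepoint)
    for arm, n_patients in zip(config.arms, config.arm_sizes):
        for i in range(n_patients):
            patient = f"{arm}{i + 1:02d}"
            for tp in config.timepoints:
                plan.append((f"{patient}_{tp}", patient, arm, tp))

    children = np.random.SeedSequence(int(config.seed)).spawn(len(plan))
    samples: dict[str, CellTable] = {}
    for (sample_id, patient, arm, tp), child in zip(plan, children):
        rng = np.random.default_rng(child)
        cells = config.cells_per_sample
        n_cells = (
            int(cells)
            if isinstance(cells, (int, np.integer))
            else int(rng.integers(cells[0], cells[1] + 1))
        )
        fracs = _sample_fractions(config, arm, tp)
        counts = rng.multinomial(n_cells, fracs)
        blocks, labels = [], []
        for pop, count, centers, p_spread, f_spread in zip(
            config.populations, counts, phen_centers, phen_spread, func_spread
        ):
            if count == 0:
                continue
            phen = rng.normal(centers, p_spread, size=(count, n_phen))
            func = rng.normal(
                _functional_means(config, pop, arm, tp), f_spread, size=(count, n_func)
            )
            blocks.append(np.hstack([phen, func]))
            labels.extend([pop.name] * count)
        values = np.vstack(blocks)
        order = rng.permutation(n_cells)
        df = pd.DataFrame(values[order], columns=list(panel.markers))
        label_series = pd.Series(np.asarray(labels, dtype=object)[order])
        samples[sample_id] = CellTable(
            sample_id, df, panel, labels=label_series, scale=ARCSINH
        )

    metadata = pd.DataFrame(
        plan, columns=["sample_id", "patient_id", "arm", "timepoint"]
    ).set_index("sample_id")
    return Study(
        samples=samples,
        metadata=metadata,
        panel=panel,
        timepoint_order=tuple(config.timepoints),
        population_compartments=config.compartments(),
    )


def small_config(**overrides) -> StudyConfig:
    """A desk-scale configuration used by demos and tests."""
    cfg = StudyConfig(
        n_patients_per_arm=6,
        timepoints=("baseline", "1h", "6h", "2wk"),
        cells_per_sample=(600, 900),
        seed=0,
    )
    return replace(cfg, **overrides) if overrides else cfg
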