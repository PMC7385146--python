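import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cytoboot as cb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return cb.default_panel()


@pytest.fixture(scope="session")
def tiny_study():
    """3 vs 3 patients, baseline + one post timepoint, no planted effect."""
    cfg = cb.StudyConfig(
        n_patients_per_arm=3,
        timepoints=("baseline", "6h"),
        cells_per_sample=400,
        seed=7,
    )
    return cb.generate_study(cfg)


@pytest.fixture(scope="session")
def effect_study():
    """6 vs 6 patients with a strong planted CD4Tmem effect at 6 h."""
    cfg = cb.StudyConfig(
        n_patients_per_arm=6,
        timepoints=("baseline", "6h"),
        cells_per_sample=800,
        seed=21,
        effects=[
            cb.EffectSpec(
                "CD4Tmem", "MP", ("6h",),
                frequency_multiplier=0.5,
                signaling_shift={"pSTAT3": 1.0},
            )
        ],
    )
    return cb.generate_study(cfg)


@pytest.fixture(scope="session")
def effect_cluster_results(effect_study):
    return cb.BootstrapClusterModel(
        effect_study, cb.ClusterConfig(K=12, B=5, seed=31)
    ).fit()


def make_separated_study(
    n_pops=3, cells=300, n_patients=2, timepoints=("baseline", "6h"), seed=5,
    spacing=8.0,
):
    """Study whose populations are point-mass-like and far apart in marker space."""
    panel = cb.default_panel()
    pops = []
    for i in range(n_pops):
        centers = {m: 0.5 for m in panel.phenotypic}
        for j, m in enumerate(panel.phenotypic):
            if j % n_pops == i:
                centers[m] = 0.5 + spacing
        pops.append(
            cb.PopulationSpec(
                name=f"pop{i}",
                compartment="adaptive" if i % 2 else "innate",
                phenotype_centers=centers,
                phenotype_spread={m: 0.25 for m in panel.phenotypic},
                functional_baseline={m: 1.0 for m in panel.functional},
                functional_spread={m: 0.3 for m in panel.functional},
                base_fraction=1.0 / n_pops,
            )
        )
    cfg = cb.StudyConfig(
        n_patients_per_arm=n_patients,
        timepoints=timepoints,
        cells_per_sample=cells,
        populations=pops,
        surgery_response={},
        seed=seed,
    )
    # empty surgery_response is replaced by the default in __post_init__; clear it
    cfg.surgery_response = {}
    return cb.generate_study(cfg)


@pytest.fixture(scope="session")
def separated_study():
    return make_separated_study()


def study_from_tables(tables, meta_rows, panel, compartments=None, timepoints=None):
    """Assemble an in-memory Study from CellTables plus (patient, arm, tp) rows."""
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "patient_id", "arm", "timepoint"]
    ).set_index("sample_id")
    if timepoints is None:
        timepoints = tuple(pd.unique(metadata["timepoint"]))
    return cb.Study(
        samples={t.sample_id: t for t in tables},
        metadata=metadata,
        panel=panel,
        timepoint_order=timepoints,
        population_compartments=dict(compartments or {}),
    )


def gaussian_cell_table(panel, sample_id, counts, centers, seed, labels=None, spread=0.3):
    """CellTable with ``counts[i]`` cells at ``centers[i]`` (phenotypic+functional)."""
    rng = np.random.default_rng(seed)
    blocks, labs = [], []
    n_markers = len(panel.markers)
    for i, (count, center) in enumerate(zip(counts, centers)):
        blocks.append(rng.normal(center, spread, size=(count, n_markers)))
        labs.extend([labels[i] if labels else f"pop{i}"] * count)
    df = pd.DataFrame(np.vstack(blocks), columns=list(panel.markers))
    return cb.CellTable(sample_id, df, panel, labels=pd.Series(labs))
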