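"""Trajectories: baseline normalization, Isomap embedding, linear extension."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import cytoboot as cb
from cytoboot.errors import ParameterError, StateError
from cytoboot.trajectories import ADAPTIVE_AXIS, INNATE_AXIS


@pytest.fixture(scope="module")
def adaptive_effect_study():
    """Signaling-only shift confined to adaptive populations (MP arm, post).

    A broad JAK/STAT attenuation-like motif across every adaptive subset: the
    shifted features form one strongly correlated direction in feature space,
    which is what makes a 1-D compartment axis able to carry it.
    """
    shift = {"pSTAT1": 0.8, "pSTAT3": 1.2, "pSTAT5": 1.2, "pSTAT6": 0.8}
    effects = [
        cb.EffectSpec(p, "MP", ("1h", "6h"), signaling_shift=dict(shift))
        for p in ("CD4Tmem", "CD4Tnaive", "CD8T", "Bcells", "Treg")
    ]
    cfg = cb.StudyConfig(
        n_patients_per_arm=10,
        timepoints=("baseline", "1h", "6h"),
        cells_per_sample=1000,
        seed=77,
        effects=effects,
    )
    return cb.generate_study(cfg)


# ---------------------------------------------------------------------------
# baseline normalization
# ---------------------------------------------------------------------------

def test_baseline_rows_map_to_zero(tiny_study):
    table, _ = cb.sample_feature_table(tiny_study)
    norm = cb.baseline_normalize(table, tiny_study)
    md = tiny_study.metadata
    base_rows = [s for s in norm.index if md.at[s, "timepoint"] == "baseline"]
    assert len(base_rows) == 6
    assert np.allclose(norm.loc[base_rows].to_numpy(), 0.0, atol=1e-12)


def test_baseline_normalize_is_idempotent(tiny_study):
    table, _ = cb.sample_feature_table(tiny_study)
    once = cb.baseline_normalize(table, tiny_study)
    twice = cb.baseline_normalize(once, tiny_study)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# Isomap
# ---------------------------------------------------------------------------

def test_isomap_preserves_order_on_a_line():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 10, size=60))
    direction = rng.normal(size=10)
    X = np.outer(t, direction)
    emb = cb.isomap_embed(X, n_neighbors=6)[:, 0]
    rho, _ = spearmanr(t, emb)
    assert abs(rho) == 1.0


def test_isomap_unrolls_quarter_circle_arc():
    theta = np.linspace(0, np.pi / 2, 100)  # arc length proportional to theta
    X = np.column_stack([np.cos(theta), np.sin(theta)])
    emb = cb.isomap_embed(X, n_neighbors=8)[:, 0]
    rho, _ = spearmanr(theta, emb)
    assert abs(rho) >= 0.99


def test_isomap_duplicate_points_coincide():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 4))
    X[7] = X[3]
    emb = cb.isomap_embed(X, n_neighbors=5)
    assert np.allclose(emb[7], emb[3], atol=1e-8)


def test_isomap_disconnected_graph_reports_component_sizes():
    rng = np.random.default_rng(2)
    X = np.vstack(
        [rng.normal(0, 0.1, size=(10, 3)), rng.normal(100, 0.1, size=(12, 3))]
    )
    with pytest.raises(StateError, match=r"\[10, 12\]|\[12, 10\]"):
        cb.isomap_embed(X, n_neighbors=3)


def test_isomap_too_few_points_errors():
    with pytest.raises(ParameterError):
        cb.isomap_embed(np.zeros((5, 2)), n_neighbors=5)


# ---------------------------------------------------------------------------
# linear extension
# ---------------------------------------------------------------------------

def test_linear_extension_exact_on_linear_manifold():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 6))
    w = rng.normal(size=6)
    y = X @ w + 2.0
    lin = cb.linear_extension(X, y)
    assert np.allclose(lin(X)[:, 0], y, atol=1e-6)


def test_linear_extension_is_affine():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 5))
    y = rng.normal(size=30)
    lin = cb.linear_extension(X, y)
    a, b = X[0], X[1]
    for alpha in (0.0, 0.3, 1.0):
        mixed = lin((alpha * a + (1 - alpha) * b)[None, :])[0, 0]
        expect = alpha * lin(a[None, :])[0, 0] + (1 - alpha) * lin(b[None, :])[0, 0]
        assert mixed == pytest.approx(expect, abs=1e-9)


def test_linear_extension_correlates_with_embedding_on_line():
    rng = np.random.default_rng(5)
    t = np.sort(rng.uniform(0, 10, size=50))
    X = np.outer(t, rng.normal(size=8))
    emb = cb.isomap_embed(X, n_neighbors=6)[:, 0]
    lin = cb.linear_extension(X, emb)
    r = np.corrcoef(lin(X)[:, 0], emb)[0, 1]
    assert r >= 0.9


# ---------------------------------------------------------------------------
# full trajectory model
# ---------------------------------------------------------------------------

def test_adaptive_only_effect_separates_along_adaptive_axis(adaptive_effect_study):
    traj = cb.ImmuneTrajectoryModel(adaptive_effect_study, n_neighbors=20).fit()
    for tp in ("1h", "6h"):
        assert traj.separation_ratio(tp) >= 3.0, tp


def test_baseline_points_coincide(adaptive_effect_study):
    traj = cb.ImmuneTrajectoryModel(adaptive_effect_study, n_neighbors=20).fit()
    emb = traj.embedding
    base = emb[emb["timepoint"] == "baseline"]
    assert base[INNATE_AXIS].std() < 1e-8
    assert base[ADAPTIVE_AXIS].std() < 1e-8


def test_jackknife_stability(adaptive_effect_study):
    """Dropping one patient barely changes the remaining coordinates' ranking."""
    study = adaptive_effect_study
    full = cb.ImmuneTrajectoryModel(study, n_neighbors=20).fit().embedding
    drop = study.metadata["patient_id"].iloc[0]
    keep_ids = study.metadata.index[study.metadata["patient_id"] != drop]
    sub = cb.Study(
        samples={s: study.samples[s] for s in keep_ids},
        metadata=study.metadata.loc[keep_ids],
        panel=study.panel,
        timepoint_order=study.timepoint_order,
        population_compartments=study.population_compartments,
    )
    part = cb.ImmuneTrajectoryModel(sub, n_neighbors=20).fit().embedding
    shared = part.index.intersection(full.index)
    for axis in (INNATE_AXIS, ADAPTIVE_AXIS):
        rho, _ = spearmanr(full.loc[shared, axis], part.loc[shared, axis])
        assert abs(rho) > 0.9


def test_interpolation_endpoints_match_linear_map(adaptive_effect_study):
    traj = cb.ImmuneTrajectoryModel(adaptive_effect_study, n_neighbors=20).fit()
    md = adaptive_effect_study.metadata
    patient = md["patient_id"].iloc[0]
    sids = md.index[md["patient_id"] == patient]
    a, b = sids[0], sids[1]
    interp = traj.interpolate(a, b, [0.0, 0.5, 1.0]).set_index("alpha")
    # endpoints equal the linear map of the endpoint samples themselves
    end1 = traj.interpolate(a, b, [1.0]).iloc[0]
    assert interp.loc[1.0, INNATE_AXIS] == pytest.approx(end1[INNATE_AXIS], abs=1e-9)
    mid = 0.5 * (interp.loc[0.0] + interp.loc[1.0])
    assert interp.loc[0.5, INNATE_AXIS] == pytest.approx(mid[INNATE_AXIS], abs=1e-9)


def test_trajectory_plot_writes_file(adaptive_effect_study, tmp_path):
    traj = cb.ImmuneTrajectoryModel(adaptive_effect_study, n_neighbors=20).fit()
    path = tmp_path / "traj.png"
    traj.plot(path=path)
    assert path.exists() and path.stat().st_size > 0
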