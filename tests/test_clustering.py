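"""Bootstrapped metaclustering: k rule, determinism, assignment, features."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import cytoboot as cb
from cytoboot.errors import ConsistencyError, DesignError

from conftest import gaussian_cell_table, make_separated_study, study_from_tables


# ---------------------------------------------------------------------------
# k rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n,k",
    [(5000, 50), (2, 1), (1, 1), (200, 10), (450, 15), (13, 3)],
)
def test_k_rule_sqrt_half_n(n, k):
    assert cb.default_k_rule(n) == k


# ---------------------------------------------------------------------------
# per-sample clustering
# ---------------------------------------------------------------------------

def test_cluster_sample_centers_stay_within_point_masses():
    """With 3 far-apart masses and k=12, no center straddles two masses."""
    rng = np.random.default_rng(0)
    masses = np.array([[0.0] * 10, [20.0] * 10, [40.0] * 10])
    X = np.vstack([rng.normal(m, 0.3, size=(100, 10)) for m in masses])
    centers, labels = cb.cluster_sample(X, 12, seed=1)
    assert centers.shape == (12, 10)
    assert labels.shape == (300,)
    d = np.linalg.norm(centers[:, None, :] - masses[None, :, :], axis=2)
    assert (d.min(axis=1) < 5.0).all()  # every center close to exactly one mass


def test_cluster_sample_k_reduced_to_n():
    X = np.random.default_rng(1).normal(size=(3, 5))
    centers, labels = cb.cluster_sample(X, 10, seed=2)
    assert centers.shape[0] == 3


# ---------------------------------------------------------------------------
# metaclustering
# ---------------------------------------------------------------------------

def test_metacluster_is_deterministic(separated_study):
    cfg = cb.ClusterConfig(K=3, B=3, seed=11)
    a = cb.BootstrapClusterModel(separated_study, cfg).fit()
    b = cb.BootstrapClusterModel(separated_study, cb.ClusterConfig(K=3, B=3, seed=11)).fit()
    for ma, mb in zip(a.models, b.models):
        assert np.array_equal(ma.centroids, mb.centroids)
        assert ma.center_assignment == mb.center_assignment
    assert a.features.equals(b.features)


def test_metacluster_recovers_separated_populations(separated_study):
    """K = number of true populations => perfect label recovery (ARI = 1)."""
    res = cb.BootstrapClusterModel(
        separated_study, cb.ClusterConfig(K=3, B=2, seed=13, exclude_neutrophils=False)
    ).fit()
    for it in range(2):
        mc = res.cell_metacluster_labels(it)
        pred, truth = [], []
        for sid in separated_study.sample_ids:
            pred.append(mc[sid])
            truth.append(separated_study.samples[sid].labels.to_numpy())
        ari = adjusted_rand_score(np.concatenate(truth), np.concatenate(pred))
        assert ari == 1.0


def test_metacluster_requires_enough_distinct_centers():
    centers = np.zeros((5, 4))  # all identical
    prov = [("s", j) for j in range(5)]
    with pytest.raises(DesignError, match="K"):
        cb.metacluster(centers, prov, cb.ClusterConfig(K=3, B=1, seed=1))


# ---------------------------------------------------------------------------
# cell assignment
# ---------------------------------------------------------------------------

def test_assign_cells_follows_center_assignment_only():
    model = cb.ClusterModel(
        iteration=0,
        centroids=np.zeros((3, 2)),
        center_assignment={("s1", 0): 2, ("s1", 1): 2, ("s2", 0): 1},
    )
    local = {"s1": np.array([0, 1, 0, -1], dtype=np.int32), "s2": np.array([0, 0], dtype=np.int32)}
    out = cb.assign_cells(local, model)
    assert out["s1"].tolist() == [2, 2, 2, -1]  # both sample-clusters map to 2
    assert out["s2"].tolist() == [1, 1]


def test_assign_cells_order_invariant():
    model = cb.ClusterModel(
        iteration=0, centroids=np.zeros((2, 2)), center_assignment={("s", 0): 1, ("s", 1): 0}
    )
    lab = np.array([0, 1, 1, 0, 0], dtype=np.int32)
    perm = np.array([4, 2, 0, 1, 3])
    direct = cb.assign_cells({"s": lab}, model)["s"]
    permuted = cb.assign_cells({"s": lab[perm]}, model)["s"]
    assert np.array_equal(direct[perm], permuted)


def test_assign_cells_unknown_cluster_errors():
    model = cb.ClusterModel(iteration=0, centroids=np.zeros((2, 2)), center_assignment={("s", 0): 0})
    with pytest.raises(ConsistencyError):
        cb.assign_cells({"s": np.array([0, 1], dtype=np.int32)}, model)


# ---------------------------------------------------------------------------
# cluster features
# ---------------------------------------------------------------------------

def _counted_study(panel, with_neutrophils):
    """One patient, two identical-structure samples with exact population counts."""
    counts = [600, 250, 150] + ([200] if with_neutrophils else [])
    centers = [0.0, 10.0, 20.0] + ([30.0] if with_neutrophils else [])
    labels = ["a", "b", "c"] + (["Neut"] if with_neutrophils else [])
    tables = [
        gaussian_cell_table(panel, "p1_base", counts, centers, 31, labels, spread=0.2),
        gaussian_cell_table(panel, "p1_post", counts, centers, 32, labels, spread=0.2),
    ]
    comp = {"a": "innate", "b": "adaptive", "c": "adaptive", "Neut": "neutrophil"}
    return study_from_tables(
        tables,
        [("p1_base", "p1", "control", "baseline"), ("p1_post", "p1", "control", "post")],
        panel,
        compartments=comp,
    )


def test_cluster_frequencies_without_neutrophils(panel):
    study = _counted_study(panel, with_neutrophils=False)
    res = cb.BootstrapClusterModel(
        study, cb.ClusterConfig(K=3, B=1, seed=41, k_rule=lambda n: 3)
    ).fit()
    freq_cols = res.column_meta["feature_type"] == "frequency"
    freqs = res.features.loc["p1_base", res.features.columns[freq_cols.to_numpy()]]
    assert sorted(np.round(freqs.to_numpy(), 9).tolist(), reverse=True) == [60.0, 25.0, 15.0]


def test_cluster_frequencies_use_total_events_denominator(panel):
    """Excluded neutrophils still count in the frequency denominator."""
    study = _counted_study(panel, with_neutrophils=True)
    res = cb.BootstrapClusterModel(
        study, cb.ClusterConfig(K=3, B=1, seed=42, k_rule=lambda n: 3)
    ).fit()
    freq_cols = res.column_meta["feature_type"] == "frequency"
    freqs = np.sort(
        res.features.loc["p1_base", res.features.columns[freq_cols.to_numpy()]].to_numpy()
    )[::-1]
    expected = np.array([600, 250, 150]) / 1200 * 100  # 50, 20.83.., 12.5
    assert np.allclose(freqs, expected, atol=1e-9)
    assert abs(freqs.sum() - 100 * 1000 / 1200) < 1e-9


def test_every_included_cell_is_clustered(effect_cluster_results):
    """Downsampling-free audit: per-sample cluster sizes add up to included cells."""
    res = effect_cluster_results
    study = res.study
    neutro = study.neutrophil_populations()
    for sid in study.sample_ids:
        labels = res.local_labels[sid]
        n_neutro = int(study.samples[sid].labels.isin(neutro).sum())
        assert (labels >= 0).sum() == study.samples[sid].n_cells - n_neutro
        assert (labels < 0).sum() == n_neutro


def test_frequency_conservation_per_sample_and_iteration(effect_cluster_results):
    res = effect_cluster_results
    study = res.study
    meta = res.column_meta
    for it in range(res.config.B):
        mask = ((meta["feature_type"] == "frequency") & (meta["iteration"] == it)).to_numpy()
        block = res.features.loc[:, res.features.columns[mask]]
        for sid in study.sample_ids:
            included = res.included_cell_count(sid)
            total = study.samples[sid].n_cells
            assert abs(block.loc[sid].sum() - 100.0 * included / total) < 1e-9


def test_identical_post_and_baseline_gives_zero_responses(panel):
    """post == baseline data => responses 0 and equal frequencies (stable k-means)."""
    base = gaussian_cell_table(panel, "p1_base", [300, 300, 300], [0.0, 10.0, 20.0], 51,
                               ["a", "b", "c"], spread=0.2)
    post = cb.CellTable("p1_post", base.data.copy(), panel, labels=base.labels.copy())
    study = study_from_tables(
        [base, post],
        [("p1_base", "p1", "control", "baseline"), ("p1_post", "p1", "control", "post")],
        panel,
        compartments={"a": "innate", "b": "adaptive", "c": "adaptive"},
    )
    res = cb.BootstrapClusterModel(
        study, cb.ClusterConfig(K=3, B=2, seed=52, k_rule=lambda n: 3)
    ).fit()
    meta = res.column_meta
    resp_mask = (meta["feature_type"] == "response").to_numpy()
    resp = res.features.loc["p1_post", res.features.columns[resp_mask]]
    assert np.allclose(resp.to_numpy(), 0.0, atol=1e-12)
    freq_mask = (meta["feature_type"] == "frequency").to_numpy()
    freq = res.features.loc[:, res.features.columns[freq_mask]]
    assert np.allclose(freq.loc["p1_base"].to_numpy(), freq.loc["p1_post"].to_numpy(), atol=1e-12)


def test_feature_group_count_is_b_times_k(effect_cluster_results):
    res = effect_cluster_results
    groups = res.column_meta.groupby(["iteration", "metacluster"]).ngroups
    assert groups == res.config.B * res.config.K


def test_features_for_timepoint_modes(effect_cluster_results):
    res = effect_cluster_results
    X_post, y_post = res.features_for_timepoint("6h")
    types = {f.split("|")[0] for f in X_post.columns.get_level_values("feature")}
    assert types == {"frequency", "response"}
    X_base, _ = res.features_for_timepoint("baseline")
    types = {f.split("|")[0] for f in X_base.columns.get_level_values("feature")}
    assert types == {"frequency", "basal"}
    assert set(y_post.unique()) == {"MP", "control"}
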