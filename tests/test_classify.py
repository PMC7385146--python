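"""Classifier stage: AUC oracle, rank-sum oracle, LOGO-CV behavior."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import cytoboot as cb
from cytoboot.errors import DesignError, ParameterError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_auc(scores, labels, positive):
    """Literal pairwise count: wins + half-ties over all (pos, neg) pairs."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == positive]
    neg = scores[np.asarray(labels) != positive]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_rank_sum_p(x, y):
    """Exhaustive two-sided p over all C(n, nx) rank assignments (tie-free)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle assumes no ties"
    ranks = rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    m = nx * ny
    lo = min(u_obs, m - u_obs)
    count = total = 0
    for comb in combinations(range(1, nx + ny + 1), nx):
        u = sum(comb) - nx * (nx + 1) / 2
        total += 1
        if u <= lo or u >= m - lo:
            count += 1
    return min(1.0, count / total)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_pairwise_example():
    scores = [0.1, 0.4, 0.35, 0.8]
    labels = ["control", "control", "MP", "MP"]
    assert cb.roc_auc(scores, labels, "MP") == 0.75  # 3 of 4 pairs won


def test_auc_perfect_separation_and_all_ties():
    assert cb.roc_auc([1, 2, 3, 4], ["c", "c", "t", "t"], "t") == 1.0
    assert cb.roc_auc([5, 5, 5, 5], ["c", "c", "t", "t"], "t") == 0.5


def test_auc_single_arm_errors():
    with pytest.raises(DesignError):
        cb.roc_auc([1, 2], ["t", "t"], "t")


@given(
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=50),
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=50),
)
def test_auc_matches_brute_force_pairwise_oracle(pos_scores, neg_scores):
    scores = pos_scores + neg_scores
    labels = ["t"] * len(pos_scores) + ["c"] * len(neg_scores)
    assert cb.roc_auc(scores, labels, "t") == pytest.approx(
        brute_force_auc(scores, labels, "t"), abs=1e-12
    )


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def test_rank_sum_exact_textbook_value():
    # 2 extreme assignments of C(6,3)=20 => p = 0.10
    assert cb.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_rank_sum_single_tied_pair_is_one():
    assert cb.wilcoxon_rank_sum([5.0], [5.0]) == 1.0


def test_rank_sum_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x, y = rng.normal(size=6), rng.normal(size=9)
        assert cb.wilcoxon_rank_sum(x, y) == pytest.approx(cb.wilcoxon_rank_sum(y, x), abs=1e-12)


def test_rank_sum_empty_input_errors():
    with pytest.raises(ParameterError):
        cb.wilcoxon_rank_sum([], [1.0])


@given(st.data())
@settings(max_examples=60)
def test_rank_sum_matches_enumeration_oracle(data):
    nx = data.draw(st.integers(1, 8))
    ny = data.draw(st.integers(1, 8))
    pooled = data.draw(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False),
            min_size=nx + ny, max_size=nx + ny, unique=True,
        )
    )
    x, y = pooled[:nx], pooled[nx:]
    assert cb.wilcoxon_rank_sum(x, y) == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# LOGO-CV ensemble
# ---------------------------------------------------------------------------

def _feature_frame(rng, n_per_arm, n_features, separation=0.0):
    n = 2 * n_per_arm
    X = rng.normal(size=(n, n_features))
    X[:n_per_arm, 0] += separation
    y = pd.Series(["MP"] * n_per_arm + ["control"] * n_per_arm,
                  index=[f"s{i}" for i in range(n)])
    return pd.DataFrame(X, index=y.index), y


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_perfectly_separating_feature_yields_auc_one(seed):
    rng = np.random.default_rng(seed)
    X, y = _feature_frame(rng, 10, 1, separation=12.0)  # one non-overlapping feature
    r = cb.TimepointClassifier(X, y, n_iter=30, n_estimators=60, seed=seed).fit()
    assert r.auc == 1.0
    assert (r.probabilities[y == "MP"] >= 0.9).all()
    assert (r.probabilities[y == "control"] <= 0.1).all()


def test_single_iteration_median_is_the_prediction():
    rng = np.random.default_rng(9)
    X, y = _feature_frame(rng, 4, 5)
    probs, iters = cb.logo_cv_predict(
        X, y, n_iter=1, seed=9, n_estimators=20, ensure_coverage=False
    )
    assert iters == 1
    # exactly half the patients were tested, each with a single prediction
    assert probs.notna().sum() == 4


def test_coverage_guarantee_tests_every_sample():
    rng = np.random.default_rng(10)
    X, y = _feature_frame(rng, 3, 5)
    probs, iters = cb.logo_cv_predict(X, y, n_iter=2, seed=10, n_estimators=20)
    assert probs.notna().all()
    assert iters >= 2


def test_null_features_auc_near_half():
    """Pure-noise features: AUC stays in [0.3, 0.7] for most seeds."""
    rng = np.random.default_rng(12)
    in_range = 0
    n_rep = 20
    for seed in range(n_rep):
        X, y = _feature_frame(rng, 12, 100)
        r = cb.TimepointClassifier(X, y, n_iter=25, n_estimators=80, seed=seed).fit()
        in_range += 0.3 <= r.auc <= 0.7
    assert in_range >= 0.7 * n_rep


def test_small_arm_design_error():
    X = pd.DataFrame(np.zeros((3, 2)), index=["a", "b", "c"])
    y = pd.Series(["MP", "control", "control"], index=X.index)
    with pytest.raises(DesignError):
        cb.logo_cv_predict(X, y, n_iter=2, seed=0)


def test_result_auc_and_p_derive_from_probabilities():
    rng = np.random.default_rng(13)
    X, y = _feature_frame(rng, 5, 10, separation=8.0)
    r = cb.TimepointClassifier(X, y, n_iter=20, n_estimators=40, seed=13).fit()
    assert r.auc == pytest.approx(
        cb.roc_auc(r.probabilities.to_numpy(), y.to_numpy(), "MP"), abs=1e-12
    )
    assert r.p_value == pytest.approx(
        cb.wilcoxon_rank_sum(
            r.probabilities[y == "MP"].to_numpy(),
            r.probabilities[y == "control"].to_numpy(),
        ),
        abs=1e-12,
    )
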