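"""Per-timepoint two-group classification.

A random-forest ensemble is evaluated with repeated leave-group-out
cross-validation (LOGO-CV): at every iteration a stratified random half of
the patients trains a forest and the held-out half is scored with the
predicted probability of belonging to the treatment arm. A sample's final
score is the *median* of its test-set predictions over all iterations in
which it was held out; iterations are extended until every sample has been
tested at least once. The per-sample median probabilities feed

* the ROC AUC, computed as the Mann-Whitney pairwise-comparison statistic,
  and
* a two-sided Wilcoxon rank-sum test of the hypothesis that the treatment
  and control probability distributions are equal.

Missing feature values (empty metaclusters) are imputed with the training
half's per-feature median inside each CV iteration, so no information flows
from test to train.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.ensemble import RandomForestClassifier

from ._utils import STAGE_CLASSIFIER, stage_seeds
from .errors import DesignError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_N_ITER = 200
DEFAULT_N_TREES = 500


def roc_auc(scores, labels, positive) -> float:
    """AUC as the Mann-Whitney statistic: P(score_pos > score_neg) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DesignError("AUC needs scores from both groups")
    ranks = rankdata(scores)  # midranks handle ties as 0.5 wins
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p-value.

    Exact enumeration (via the Mann-Whitney count distribution) when the
    pooled size is at most 20 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections. Symmetric in (x, y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # fully tied: the null cannot be rejected at all
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # degenerate tie structure under the normal approximation
        return 1.0
    return min(p, 1.0)


def _stratified_half_split(groups: dict[str, np.ndarray], rng: np.random.Generator):
    """Random half split preserving arm proportions; returns (train, test)."""
    train, test = [], []
    for idx in groups.values():
        perm = rng.permutation(idx)
        n_train = (len(perm) + 1) // 2
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.asarray(train), np.asarray(test)


def logo_cv_predict(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
    positive: str | None = None,
    ensure_coverage: bool = True,
) -> tuple[pd.Series, int]:
    """Repeated leave-group-out RF predictions; returns (median probs, iterations).

    ``X`` has one row per patient (sample) at one timepoint; ``y`` holds the
    arm labels. With ``ensure_coverage`` (default) extra iterations are drawn
    until every sample has at least one test-set prediction.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    y = pd.Series(y).astype(str)
    labels = sorted(y.unique())
    if len(labels) != 2:
        raise DesignError(f"need exactly two arms, got {labels}")
    if positive is None:
        others = [l for l in labels if l != "control"]
        positive = others[0] if len(others) == 1 else labels[1]
    groups = {
        lab: np.flatnonzero((y == lab).to_numpy()) for lab in labels
    }
    for lab, idx in groups.items():
        if len(idx) < 2:
            raise DesignError(f"arm {lab!r} has {len(idx)} patient(s); need >= 2")

    all_missing = X.columns[X.isna().all(axis=0)]
    if len(all_missing):
        log.warning("dropping %d all-missing feature column(s)", len(all_missing))
        X = X.drop(columns=all_missing)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()

    rng_seed, forest_entropy = stage_seeds(seed, STAGE_CLASSIFIER, 2)
    rng = np.random.default_rng(rng_seed)
    forest_seeds = iter(stage_seeds(forest_entropy, STAGE_CLASSIFIER, n_iter + 1000))

    predictions: list[list[float]] = [[] for _ in range(len(y))]
    iterations = 0

    def _one_iteration():
        nonlocal iterations
        train, test = _stratified_half_split(groups, rng)
        med = np.nanmedian(Xv[train], axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        Xtr = np.where(np.isnan(Xv[train]), med, Xv[train])
        Xte = np.where(np.isnan(Xv[test]), med, Xv[test])
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=next(forest_seeds),
            n_jobs=1,
        )
        clf.fit(Xtr, yv[train])
        pos_col = list(clf.classes_).index(positive)
        proba = clf.predict_proba(Xte)[:, pos_col]
        for i, p in zip(test, proba):
            predictions[i].append(float(p))
        iterations += 1

    for _ in range(n_iter):
        _one_iteration()
    if ensure_coverage:
        extra = 0
        while any(len(p) == 0 for p in predictions):
            if extra >= 1000:
                raise DesignError("could not achieve test coverage for every sample")
            _one_iteration()
            extra += 1

    uncovered = [X.index[i] for i, p in enumerate(predictions) if len(p) == 0]
    if uncovered:
        log.warning("samples never tested (coverage disabled): %s", uncovered)
    probs = pd.Series(
        [np.median(p) if p else np.nan for p in predictions],
        index=X.index,
        name="probability",
    )
    return probs, iterations


@dataclass
class ClassifierResult:
    """LOGO-CV outcome at one timepoint."""

    timepoint: str
    probabilities: pd.Series  # per-sample median predicted treatment probability
    labels: pd.Series
    positive: str
    auc: float
    p_value: float
    n_iterations: int

    def summary(self) -> str:
        n_pos = int((self.labels == self.positive).sum())
        n_neg = len(self.labels) - n_pos
        lines = [
            f"Leave-group-out classification @ {self.timepoint}",
            "-" * 46,
            f"arms:        {self.positive} (n={n_pos}) vs rest (n={n_neg})",
            f"iterations:  {self.n_iterations}",
            f"AUC:         {self.auc:.3f}",
            f"p (rank-sum) {self.p_value:.3g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "timepoint": self.timepoint,
            "positive": self.positive,
            "auc": self.auc,
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "probabilities": {str(k): float(v) for k, v in self.probabilities.items()},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class TimepointClassifier:
    """Two-group LOGO-CV random-forest model for one timepoint's features."""

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        *,
        timepoint: str = "",
        n_iter: int = DEFAULT_N_ITER,
        n_estimators: int = DEFAULT_N_TREES,
        seed: int = 0,
        positive: str | None = None,
        ensure_coverage: bool = True,
    ):
        self.X = X
        self.y = pd.Series(y).astype(str)
        self.timepoint = timepoint
        self.n_iter = n_iter
        self.n_estimators = n_estimators
        self.seed = seed
        self.positive = positive
        self.ensure_coverage = ensure_coverage

    def fit(self) -> ClassifierResult:
        probs, iters = logo_cv_predict(
            self.X,
            self.y,
            n_iter=self.n_iter,
            seed=self.seed,
            n_estimators=self.n_estimators,
            positive=self.positive,
            ensure_coverage=self.ensure_coverage,
        )
        labels = sorted(self.y.unique())
        positive = self.positive
        if positive is None:
            others = [l for l in labels if l != "control"]
            positive = others[0] if len(others) == 1 else labels[1]
        tested = probs.dropna()
        yt = self.y.loc[tested.index]
        auc = roc_auc(tested.to_numpy(), yt.to_numpy(), positive)
        p = wilcoxon_rank_sum(
            tested[yt == positive].to_numpy(), tested[yt != positive].to_numpy()
        )
        return ClassifierResult(
            timepoint=self.timepoint,
            probabilities=probs,
            labels=self.y,
            positive=positive,
            auc=auc,
            p_value=p,
            n_iterations=iters,
        )
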