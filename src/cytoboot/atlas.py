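"""Two-dimensional immune-cell atlas.

Every (iteration, metacluster) is represented by the median expression of its
pooled cells over the phenotypic markers; PCA (centering only — all markers
share arcsinh units) projects the clusters to two dimensions. Per-cluster
two-group statistics are then painted onto this map:

* ``best_logp`` — the largest -log10 rank-sum p over all of a cluster's
  frequency/signaling features at a timepoint, and
* ``signed_logp`` — sign(r) * -log10 p per feature, where sign(r) is +1 when
  the feature's mean is higher in the treatment arm, -1 when higher in
  control, and 0 on an exact tie.

No multiple-testing correction is applied by default (the raw best-p map is
the reported statistic); a Benjamini-Hochberg layer is available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

from .classify import wilcoxon_rank_sum
from .clustering import ClusterResults
from .errors import DesignError, ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def pca_coordinates(medians: pd.DataFrame) -> pd.DataFrame:
    """First two principal components of a clusters x markers median matrix."""
    if medians.shape[0] < 3:
        raise DesignError("PCA atlas needs at least 3 clusters")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(medians.to_numpy())
    out = pd.DataFrame(coords, index=medians.index, columns=["PC1", "PC2"])
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out


@dataclass
class AtlasCoordinates:
    """Cluster medians and their 2-D PCA projection."""

    medians: pd.DataFrame  # (iteration, metacluster) x phenotypic markers
    coords: pd.DataFrame   # (iteration, metacluster) x [PC1, PC2]


def compute_atlas_coordinates(results: ClusterResults) -> AtlasCoordinates:
    """Atlas backbone from a fitted metaclustering."""
    medians = results.pooled_cluster_medians()
    return AtlasCoordinates(medians=medians, coords=pca_coordinates(medians))


# ---------------------------------------------------------------------------
# per-cluster group statistics
# ---------------------------------------------------------------------------

def _sign_of_difference(pos_mean: float, neg_mean: float) -> int:
    if np.isnan(pos_mean) or np.isnan(neg_mean) or pos_mean == neg_mean:
        return 0
    return 1 if pos_mean > neg_mean else -1


@dataclass
class GroupComparisonResult:
    """Rank-sum statistics for every (iteration, metacluster, feature)."""

    timepoint: str
    positive: str
    table: pd.DataFrame  # iteration, metacluster, feature_type, marker, p, sign_r, signed_logp
    best: pd.DataFrame   # (iteration, metacluster) -> best_logp

    def bh_adjusted(self) -> pd.DataFrame:
        """Optional Benjamini-Hochberg layer over the per-feature p-values."""
        tab = self.table.copy()
        p = tab["p"].to_numpy()
        order = np.argsort(p)
        n = len(p)
        adj = np.empty(n)
        adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        tab["p_bh"] = np.minimum(adj, 1.0)
        return tab

    def save_csv(self, path) -> None:
        tab = self.table.copy()
        tab["timepoint"] = self.timepoint
        tab = tab.merge(
            self.best.rename("best_logp"),
            left_on=["iteration", "metacluster"],
            right_index=True,
        )
        tab.to_csv(path, index=False)


def per_cluster_group_stats(
    results: ClusterResults,
    timepoint: str,
    *,
    positive: str | None = None,
    mode: str | None = None,
) -> GroupComparisonResult:
    """Two-group rank-sum statistics for every cluster feature at a timepoint.

    Features missing in more than half of either arm are excluded (with a
    logged count) rather than tested on fragmentary data.
    """
    X, y = results.features_for_timepoint(timepoint, mode=mode)
    labels = sorted(y.unique())
    if len(labels) != 2:
        raise DesignError(f"need both arms at {timepoint!r}, got {labels}")
    if positive is None:
        others = [l for l in labels if l != "control"]
        positive = others[0] if len(others) == 1 else labels[1]
    pos_mask = (y == positive).to_numpy()
    Xv = X.to_numpy(dtype=float)
    pos_rows, neg_rows = Xv[pos_mask], Xv[~pos_mask]

    meta = results.column_meta.loc[
        results.column_meta["feature_type"].isin(
            {f.split("|")[0] for f in X.columns.get_level_values("feature")}
        )
    ].reset_index(drop=True)
    assert len(meta) == X.shape[1]

    half_pos, half_neg = pos_rows.shape[0] / 2.0, neg_rows.shape[0] / 2.0
    records = []
    n_excluded = 0
    for j in range(Xv.shape[1]):
        xp = pos_rows[:, j]
        xn = neg_rows[:, j]
        xp_ok, xn_ok = xp[~np.isnan(xp)], xn[~np.isnan(xn)]
        if (len(xp) - len(xp_ok)) > half_pos or (len(xn) - len(xn_ok)) > half_neg:
            n_excluded += 1
            continue
        if len(xp_ok) == 0 or len(xn_ok) == 0:
            n_excluded += 1
            continue
        p = wilcoxon_rank_sum(xp_ok, xn_ok)
        sign_r = _sign_of_difference(float(np.mean(xp_ok)), float(np.mean(xn_ok)))
        records.append(
            (
                int(meta.at[j, "iteration"]),
                int(meta.at[j, "metacluster"]),
                meta.at[j, "feature_type"],
                meta.at[j, "marker"],
                p,
                sign_r,
                sign_r * -np.log10(p),
            )
        )
    if n_excluded:
        log.warning(
            "%s: excluded %d feature(s) missing in more than half of an arm",
            timepoint, n_excluded,
        )
    table = pd.DataFrame(
        records,
        columns=["iteration", "metacluster", "feature_type", "marker", "p", "sign_r", "signed_logp"],
    )
    best = (
        (-np.log10(table["p"]))
        .groupby([table["iteration"], table["metacluster"]])
        .max()
        .rename("best_logp")
    )
    return GroupComparisonResult(
        timepoint=timepoint, positive=positive, table=table, best=best
    )


def top_cluster_enrichment(
    best: pd.Series,
    composition: pd.DataFrame,
    population: str,
    *,
    top_fraction: float = 0.1,
) -> tuple[float, pd.Index]:
    """Hypergeometric enrichment of a population in the top best-p clusters.

    Ranks clusters by ``best_logp``, takes the top ``top_fraction`` and tests
    (one-sided) whether cells of ``population`` are over-represented in those
    clusters relative to the study-wide composition. Returns ``(p, top_index)``.
    """
    best = best.sort_values(ascending=False)
    n_top = max(1, int(np.ceil(top_fraction * len(best))))
    top_idx = best.index[:n_top]
    comp = composition.reindex(best.index).fillna(0)
    pop_cells = comp[population] if population in comp.columns else pd.Series(0, index=comp.index)
    a = int(pop_cells.loc[top_idx].sum())           # population cells in top clusters
    top_total = int(comp.loc[top_idx].to_numpy().sum())
    pop_total = int(pop_cells.sum())
    grand_total = int(comp.to_numpy().sum())
    p = float(hypergeom.sf(a - 1, grand_total, pop_total, top_total))
    return p, top_idx


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_atlas(
    coords: AtlasCoordinates,
    stats: GroupComparisonResult | None = None,
    mode: str = "best_p",
    *,
    path=None,
    ax=None,
):
    """Scatter the clusters at (PC1, PC2) colored by the chosen statistic.

    Modes: ``best_p`` (viridis, -log10 of the best univariate p),
    ``signed:<feature>`` (diverging palette symmetric about 0; blue = higher
    in the treatment arm), or ``phenotype:<marker>`` (median marker level).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    xy = coords.coords

    if mode == "best_p":
        if stats is None:
            raise ParameterError("best_p mode needs group statistics")
        values = stats.best.reindex(xy.index).fillna(0.0)
        sc = ax.scatter(xy["PC1"], xy["PC2"], c=values, cmap="viridis", s=25)
        fig.colorbar(sc, ax=ax, label="best -log10 p")
        title = f"best univariate p @ {stats.timepoint}"
    elif mode.startswith("signed:"):
        if stats is None:
            raise ParameterError("signed mode needs group statistics")
        feature = mode.split(":", 1)[1]
        ft, _, marker = feature.partition("|")
        tab = stats.table
        sel = tab[(tab["feature_type"] == ft) & (tab["marker"] == marker)]
        values = (
            sel.set_index(["iteration", "metacluster"])["signed_logp"]
            .reindex(xy.index)
            .fillna(0.0)
        )
        vmax = max(float(values.abs().max()), 1e-12)
        sc = ax.scatter(
            xy["PC1"], xy["PC2"], c=values, cmap="RdBu", vmin=-vmax, vmax=vmax, s=25
        )
        fig.colorbar(sc, ax=ax, label=f"sign(r) * -log10 p [{feature}]")
        title = f"{feature} @ {stats.timepoint}"
    elif mode.startswith("phenotype:"):
        marker = mode.split(":", 1)[1]
        if marker not in coords.medians.columns:
            raise ParameterError(f"unknown phenotypic marker {marker!r}")
        sc = ax.scatter(
            xy["PC1"], xy["PC2"], c=coords.medians[marker], cmap="viridis", s=25
        )
        fig.colorbar(sc, ax=ax, label=f"median {marker} (arcsinh)")
        title = f"phenotype: {marker}"
    else:
        raise ParameterError(f"unknown atlas mode {mode!r}")

    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# model / results wrapper
# ---------------------------------------------------------------------------

class ImmuneAtlas:
    """Atlas model over a fitted metaclustering."""

    def __init__(self, results: ClusterResults):
        self.results = results

    def fit(self) -> "AtlasResult":
        return AtlasResult(self.results, compute_atlas_coordinates(self.results))


@dataclass
class AtlasResult:
    results: ClusterResults
    coordinates: AtlasCoordinates

    def group_stats(self, timepoint: str, **kw) -> GroupComparisonResult:
        return per_cluster_group_stats(self.results, timepoint, **kw)

    def plot(self, stats=None, mode="best_p", path=None, ax=None):
        return render_atlas(self.coordinates, stats, mode, path=path, ax=ax)

    def summary(self) -> str:
        evr = self.coordinates.coords.attrs.get("explained_variance_ratio", [])
        lines = [
            "Immune cell atlas",
            "-----------------",
            f"clusters embedded: {len(self.coordinates.coords)}",
            f"PC1/PC2 variance:  " + ", ".join(f"{v:.1%}" for v in evr),
        ]
        return "\n".join(lines)
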