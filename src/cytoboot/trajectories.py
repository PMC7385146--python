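"""Innate/adaptive immune-trajectory embedding.

Per-sample population features (gated frequencies plus baseline-subtracted
signaling responses) are split into innate and adaptive compartments, each
patient's baseline vector is subtracted so every baseline maps to the origin,
and each compartment is embedded separately into one Isomap dimension. The
two coordinates form per-patient trajectories along an innate (X) and an
adaptive (Y) axis over the post-surgery timepoints. Because frequencies
(percent units) and signaling responses (arcsinh units) live on incommensurate
scales, each feature is scaled to unit variance across samples after baseline
subtraction (``standardize=False`` disables this); without it either axis
would simply track the feature family with the larger numeric range.
Eigen-embeddings are sign-ambiguous, so each axis is oriented so that the
group-median coordinate of the first post-baseline timepoint is at least the
baseline median. A
least-squares linear map from feature space to each coordinate supports
continuous interpolation between consecutive timepoints (for animations) —
an affine extension, not an out-of-sample Isomap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

from .data import Study
from .errors import ParameterError, StateError
from .features import population_frequencies, population_signaling
from .simulate import NEUTROPHIL

log = logging.getLogger(__name__)

DEFAULT_N_NEIGHBORS = 10
INNATE_AXIS = "x_innate"
ADAPTIVE_AXIS = "y_adaptive"


# ---------------------------------------------------------------------------
# feature table construction
# ---------------------------------------------------------------------------

def sample_feature_table(
    study: Study,
    compartment_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-sample gated feature vectors and their compartment assignment.

    Columns are ``freq|<population>`` and ``resp|<population>|<marker>``;
    response features of baseline samples are zero by definition. The
    compartment of a feature follows its population; neutrophils count as
    innate (per-feature overrides can be supplied via ``compartment_map``).
    Missing values (empty populations) are filled with 0 after a logged count.
    """
    freq = population_frequencies(study)
    _, resp = population_signaling(study)

    freq_wide = freq.pivot(index="sample_id", columns="population", values="value")
    freq_wide.columns = [f"freq|{p}" for p in freq_wide.columns]
    resp_wide = resp.pivot(
        index="sample_id", columns=["population", "marker"], values="value"
    )
    resp_wide.columns = [f"resp|{p}|{m}" for p, m in resp_wide.columns]
    table = freq_wide.join(resp_wide, how="left")
    # baseline samples have no response rows; their responses are zero
    table = table.reindex(study.sample_ids)
    n_missing = int(table.isna().to_numpy().sum())
    if n_missing:
        log.info("feature table: %d missing value(s) filled with 0", n_missing)
    table = table.fillna(0.0)

    pop_comp = {
        p: (c if c != NEUTROPHIL else "innate")
        for p, c in study.population_compartments.items()
    }
    feat_comp: dict[str, str] = {}
    for col in table.columns:
        pop = col.split("|")[1]
        comp = pop_comp.get(pop)
        if comp is None:
            raise StateError(f"population {pop!r} has no compartment assignment")
        feat_comp[col] = comp
    if compartment_map:
        feat_comp.update(compartment_map)
    return table, feat_comp


def baseline_normalize(table: pd.DataFrame, study: Study) -> pd.DataFrame:
    """Subtract each patient's baseline row; baselines map to the zero vector.

    Patients without a baseline sample are excluded with a logged warning.
    """
    md = study.metadata
    out = {}
    skipped = []
    for sid in table.index:
        patient = md.at[sid, "patient_id"]
        base_sid = study.baseline_sample_of(patient)
        if base_sid is None or base_sid not in table.index:
            skipped.append(patient)
            continue
        out[sid] = table.loc[sid] - table.loc[base_sid]
    if skipped:
        log.warning("patients without baseline excluded: %s", sorted(set(skipped)))
    return pd.DataFrame(out).T.loc[[s for s in table.index if s in out]]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def isomap_embed(
    vectors: np.ndarray,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    n_components: int = 1,
) -> np.ndarray:
    """Classical Isomap: k-NN graph, geodesic distances, MDS eigen-embedding."""
    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < n_neighbors + 2:
        raise ParameterError(
            f"Isomap needs at least n_neighbors + 2 = {n_neighbors + 2} points, got {X.shape[0]}"
        )
    graph = kneighbors_graph(X, n_neighbors, mode="connectivity")
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise StateError(
            f"neighborhood graph is disconnected ({n_comp} components, sizes {sizes}); "
            "increase n_neighbors"
        )
    emb = Isomap(
        n_neighbors=n_neighbors, n_components=n_components, eigen_solver="dense"
    ).fit_transform(X)
    return emb


@dataclass
class LinearMap:
    """Affine feature-space -> coordinate map fitted by least squares."""

    coef: np.ndarray
    intercept: np.ndarray

    def __call__(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def linear_extension(vectors: np.ndarray, embedding: np.ndarray) -> LinearMap:
    """Least-squares linear map reproducing the embedding from features.

    Rank-deficient feature matrices fall back to a lightly ridge-regularized
    solve with a warning.
    """
    X = np.asarray(vectors, dtype=float)
    Y = np.asarray(embedding, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    A = np.hstack([X, np.ones((X.shape[0], 1))])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        log.warning("feature matrix is rank-deficient; using ridge-regularized fit")
        ata = A.T @ A + 1e-8 * np.eye(A.shape[1])
        theta = np.linalg.solve(ata, A.T @ Y)
    else:
        theta, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return LinearMap(coef=theta[:-1], intercept=theta[-1])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ImmuneTrajectoryModel:
    """Two-axis (innate X, adaptive Y) trajectory embedding of a study."""

    def __init__(
        self,
        study: Study,
        *,
        n_neighbors: int = DEFAULT_N_NEIGHBORS,
        compartment_map: dict[str, str] | None = None,
        standardize: bool = True,
        positive: str | None = None,
    ):
        self.study = study
        self.n_neighbors = n_neighbors
        self.compartment_map = compartment_map
        self.standardize = standardize
        self.positive = positive

    def fit(self) -> "TrajectoryResult":
        study = self.study
        table, feat_comp = sample_feature_table(study, self.compartment_map)
        normalized = baseline_normalize(table, study)
        if self.standardize:
            sd = normalized.std(ddof=1)
            sd = sd.where(sd > 1e-12, 1.0)  # constant columns stay as-is
            normalized = normalized / sd
        md = study.metadata.loc[normalized.index]

        n_points = normalized.shape[0]
        k = self.n_neighbors
        if n_points < k + 2:
            k = max(1, n_points - 2)
            log.warning(
                "only %d points; reducing Isomap n_neighbors from %d to %d",
                n_points, self.n_neighbors, k,
            )

        tp_order = list(study.timepoint_order)
        baseline_tp = tp_order[0]
        first_post = tp_order[1] if len(tp_order) > 1 else None

        coords = {}
        maps = {}
        axes = {INNATE_AXIS: "innate", ADAPTIVE_AXIS: "adaptive"}
        for axis, compartment in axes.items():
            cols = [c for c, comp in feat_comp.items() if comp == compartment]
            if not cols:
                raise StateError(f"no features assigned to the {compartment} compartment")
            X = normalized[cols].to_numpy()
            coord = isomap_embed(X, n_neighbors=k, n_components=1)[:, 0]
            # orientation convention: first post-baseline group median >= baseline median
            if first_post is not None:
                base_med = np.median(coord[(md["timepoint"] == baseline_tp).to_numpy()])
                post_med = np.median(coord[(md["timepoint"] == first_post).to_numpy()])
                if post_med < base_med:
                    coord = -coord
            coords[axis] = coord
            maps[axis] = linear_extension(X, coord)

        embedding = pd.DataFrame(
            {
                "patient_id": md["patient_id"].to_numpy(),
                "arm": md["arm"].to_numpy(),
                "timepoint": md["timepoint"].to_numpy(),
                INNATE_AXIS: coords[INNATE_AXIS],
                ADAPTIVE_AXIS: coords[ADAPTIVE_AXIS],
            },
            index=normalized.index,
        )
        return TrajectoryResult(
            study=study,
            embedding=embedding,
            normalized_features=normalized,
            feature_compartments=feat_comp,
            linear_maps=maps,
            n_neighbors=k,
        )


@dataclass
class TrajectoryResult:
    study: Study
    embedding: pd.DataFrame  # sample_id -> patient, arm, timepoint, x_innate, y_adaptive
    normalized_features: pd.DataFrame
    feature_compartments: dict[str, str]
    linear_maps: dict[str, LinearMap]
    n_neighbors: int

    def median_trajectories(self) -> pd.DataFrame:
        """Group-median (arm, timepoint) coordinates, timepoints in study order."""
        med = (
            self.embedding.groupby(["arm", "timepoint"], sort=False)[
                [INNATE_AXIS, ADAPTIVE_AXIS]
            ]
            .median()
            .reset_index()
        )
        order = {tp: i for i, tp in enumerate(self.study.timepoint_order)}
        return med.sort_values(["arm", "timepoint"], key=lambda s: s.map(order).fillna(s)).reset_index(drop=True)

    def separation_ratio(self, timepoint: str) -> float:
        """|adaptive-axis arm separation| / |innate-axis arm separation| at a timepoint."""
        med = self.median_trajectories()
        rows = med[med["timepoint"] == timepoint].set_index("arm")
        arms = list(rows.index)
        if len(arms) != 2:
            raise StateError(f"need both arms at {timepoint!r}")
        dy = abs(rows[ADAPTIVE_AXIS].iloc[0] - rows[ADAPTIVE_AXIS].iloc[1])
        dx = abs(rows[INNATE_AXIS].iloc[0] - rows[INNATE_AXIS].iloc[1])
        return float(dy / dx) if dx > 0 else float("inf")

    def interpolate(self, sample_a: str, sample_b: str, alphas) -> pd.DataFrame:
        """Linear-map coordinates of convex combinations of two samples."""
        xa = self.normalized_features.loc[sample_a].to_numpy()
        xb = self.normalized_features.loc[sample_b].to_numpy()
        rows = []
        comp_cols = {
            axis: [c for c, comp in self.feature_compartments.items() if comp == comp_name]
            for axis, comp_name in ((INNATE_AXIS, "innate"), (ADAPTIVE_AXIS, "adaptive"))
        }
        cols = list(self.normalized_features.columns)
        idx = {c: i for i, c in enumerate(cols)}
        for alpha in np.atleast_1d(alphas):
            x = alpha * xa + (1 - alpha) * xb
            row = {"alpha": float(alpha)}
            for axis in (INNATE_AXIS, ADAPTIVE_AXIS):
                sel = [idx[c] for c in comp_cols[axis]]
                row[axis] = float(self.linear_maps[axis](x[sel][None, :])[0, 0])
            rows.append(row)
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.embedding.rename_axis("sample_id").to_csv(path)

    def plot(self, path=None, ax=None):
        """Per-patient trajectories over time along the two axes."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(6, 5))
        else:
            fig = ax.figure
        order = {tp: i for i, tp in enumerate(self.study.timepoint_order)}
        colors = {arm: c for arm, c in zip(sorted(self.embedding["arm"].unique()), ("black", "crimson"))}
        for patient, grp in self.embedding.groupby("patient_id"):
            grp = grp.sort_values("timepoint", key=lambda s: s.map(order))
            ax.plot(
                grp[INNATE_AXIS], grp[ADAPTIVE_AXIS],
                color=colors[grp["arm"].iloc[0]], alpha=0.35, lw=0.8,
            )
        med = self.median_trajectories()
        for arm, grp in med.groupby("arm"):
            ax.plot(
                grp[INNATE_AXIS], grp[ADAPTIVE_AXIS],
                color=colors[arm], lw=2.5, marker="o", label=arm,
            )
        ax.set_xlabel("innate axis (X)")
        ax.set_ylabel("adaptive axis (Y)")
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig

    def summary(self) -> str:
        lines = [
            "Immune trajectory embedding",
            "---------------------------",
            f"points embedded: {len(self.embedding)}",
            f"n_neighbors:     {self.n_neighbors}",
            f"innate features:  {sum(1 for c in self.feature_compartments.values() if c == 'innate')}",
            f"adaptive features:{sum(1 for c in self.feature_compartments.values() if c == 'adaptive')}",
        ]
        return "\n".join(lines)
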