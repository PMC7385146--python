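"""Downsampling-free bootstrapped metaclustering.

The algorithm integrates every cell of every sample without downsampling:

1. each sample is coarsely clustered on the phenotypic markers with k-means,
   using ``k = round(sqrt(N/2))`` clusters where N is the sample's cell count
   (after neutrophil exclusion when enabled);
2. the per-sample cluster centers are concatenated into one matrix and
   repeatedly clustered with k-means into ``K`` metaclusters, ``B``
   independent times, to absorb run-to-run clustering variability;
3. each cell inherits the metacluster of its sample-level cluster center — no
   cell-level distance computation is ever done;
4. per (sample, iteration, metacluster) features are built: the metacluster's
   frequency as a percentage of the sample's *total* events (including any
   excluded neutrophils), the median arcsinh intensity of every functional
   marker ("basal"), and the baseline-subtracted response (post-baseline
   median minus the same patient's baseline median, within the same
   iteration's cluster definition).

The feature matrix concatenates all B iterations' columns; metaclusters empty
in a sample yield missing medians, never zeros.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._utils import STAGE_METACLUSTER, STAGE_SAMPLE_KMEANS, round_half_away, stage_seeds
from .data import Study
from .errors import ConsistencyError, DesignError, StateError
from .panel import FUNCTIONAL, PHENOTYPIC

log = logging.getLogger(__name__)

FREQUENCY = "frequency"
BASAL = "basal"
RESPONSE = "response"


def default_k_rule(n_cells: int) -> int:
    """``round(sqrt(N/2))`` (half away from zero), floored at 1."""
    return max(1, round_half_away(math.sqrt(n_cells / 2.0)))


@dataclass
class ClusterConfig:
    """Knobs of the bootstrapped metaclustering stage."""

    K: int = 30                 # metacluster count
    B: int = 200                # bootstrap metaclustering iterations
    k_rule: Callable[[int], int] = default_k_rule
    exclude_neutrophils: bool = True
    seed: int = 0
    n_init: int = 10            # k-means restarts per run
    tol: float = 1e-4
    include_basal: bool = True  # basal median columns (baseline-timepoint classifier)

    def validate(self) -> None:
        if self.K < 2:
            raise DesignError("K must be >= 2")
        if self.B < 1:
            raise DesignError("B must be >= 1")


@dataclass
class ClusterModel:
    """One metaclustering iteration: centroids plus center -> metacluster map."""

    iteration: int
    centroids: np.ndarray  # K x P over phenotypic markers, arcsinh units
    center_assignment: dict[tuple[str, int], int]

    def __post_init__(self):
        if not np.isfinite(self.centroids).all():
            raise ConsistencyError("metacluster centroids contain non-finite values")


def cluster_sample(
    values: np.ndarray,
    k: int,
    seed: int,
    *,
    n_init: int = 10,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means one sample's phenotypic matrix; returns (centers, labels)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 1:
        raise StateError("cannot cluster an empty sample")
    if k > n:
        log.warning("requested k=%d exceeds N=%d cells; reducing k to N", k, n)
        k = n
    km = KMeans(
        n_clusters=k, n_init=n_init, tol=tol, random_state=int(seed)
    ).fit(values)
    return km.cluster_centers_, km.labels_.astype(np.int32)


def metacluster(
    all_centers: np.ndarray,
    provenance: list[tuple[str, int]],
    config: ClusterConfig,
) -> list[ClusterModel]:
    """Cluster the stacked sample centers into K metaclusters, B times."""
    config.validate()
    all_centers = np.asarray(all_centers, dtype=float)
    if all_centers.shape[0] != len(provenance):
        raise ConsistencyError("provenance length does not match center count")
    n_distinct = np.unique(all_centers, axis=0).shape[0]
    if n_distinct < config.K:
        raise DesignError(
            f"only {n_distinct} distinct sample-cluster centers; choose K <= {n_distinct}"
        )
    seeds = stage_seeds(config.seed, STAGE_METACLUSTER, config.B)
    models = []
    for b in range(config.B):
        km = KMeans(
            n_clusters=config.K,
            n_init=config.n_init,
            tol=config.tol,
            random_state=seeds[b],
        ).fit(all_centers)
        assignment = {
            prov: int(lab) for prov, lab in zip(provenance, km.labels_)
        }
        models.append(
            ClusterModel(
                iteration=b,
                centroids=km.cluster_centers_.copy(),
                center_assignment=assignment,
            )
        )
    return models


def assign_cells(
    local_labels: dict[str, np.ndarray],
    model: ClusterModel,
) -> dict[str, np.ndarray]:
    """Map per-cell sample-cluster labels to metacluster labels.

    Excluded cells (label -1) stay -1. A cell's metacluster is the metacluster
    of its sample-cluster center; no distances are computed at cell level.
    """
    out = {}
    for sid, labels in local_labels.items():
        n_local = int(labels.max()) + 1 if labels.size and labels.max() >= 0 else 0
        lookup = np.empty(n_local, dtype=np.int32)
        for j in range(n_local):
            try:
                lookup[j] = model.center_assignment[(sid, j)]
            except KeyError:
                raise ConsistencyError(
                    f"sample-cluster ({sid!r}, {j}) unknown to iteration {model.iteration}"
                ) from None
        mapped = np.full(labels.shape, -1, dtype=np.int32)
        keep = labels >= 0
        mapped[keep] = lookup[labels[keep]]
        out[sid] = mapped
    return out


def _grouped_medians(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Median of ``values`` rows per label in [0, k); NaN for empty groups."""
    out = np.full((k, values.shape[1]), np.nan)
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    bounds = np.searchsorted(sorted_labels, np.arange(k + 1))
    for c in range(k):
        lo, hi = bounds[c], bounds[c + 1]
        if hi > lo:
            out[c] = np.median(values[order[lo:hi]], axis=0)
    return out


def build_cluster_features(
    study: Study,
    models: list[ClusterModel],
    local_labels: dict[str, np.ndarray],
    *,
    include_basal: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x (iteration, metacluster, feature) matrix plus column metadata.

    Frequencies are percentages of each sample's total events (neutrophils
    included in the denominator even when excluded from clustering); responses
    subtract the same patient's baseline median within the same iteration.
    """
    sids = study.sample_ids
    func = list(study.panel.functional)
    n_func = len(func)
    K = models[0].centroids.shape[0] if models else 0
    B = len(models)
    S = len(sids)

    func_vals = {}
    incl_labels = {}
    total_events = np.empty(S)
    for s, sid in enumerate(sids):
        ct = study.samples[sid]
        lab = local_labels[sid]
        keep = lab >= 0
        func_vals[sid] = ct.functional_values()[keep]
        incl_labels[sid] = lab[keep]
        total_events[s] = ct.n_cells

    freq = np.zeros((B, S, K))
    med = np.full((B, S, K, n_func), np.nan)
    for b, model in enumerate(models):
        mc_labels = assign_cells(local_labels, model)
        for s, sid in enumerate(sids):
            ml = mc_labels[sid][mc_labels[sid] >= 0]
            counts = np.bincount(ml, minlength=K)
            freq[b, s] = 100.0 * counts / total_events[s]
            med[b, s] = _grouped_medians(func_vals[sid], ml, K)

    # baseline-subtracted responses, iteration-matched
    baseline_idx = np.full(S, -1, dtype=int)
    pos = {sid: s for s, sid in enumerate(sids)}
    baseline_tp = study.baseline_timepoint
    for s, sid in enumerate(sids):
        md = study.metadata.loc[sid]
        if md["timepoint"] == baseline_tp:
            continue
        base_sid = study.baseline_sample_of(md["patient_id"])
        if base_sid is not None:
            baseline_idx[s] = pos[base_sid]
    resp = np.full_like(med, np.nan)
    has_base = baseline_idx >= 0
    resp[:, has_base] = med[:, has_base] - med[:, baseline_idx[has_base]]

    # assemble the wide matrix, iteration-major column order
    blocks = []
    col_meta = []
    for b in range(B):
        for c in range(K):
            blocks.append(freq[b, :, c : c + 1])
            col_meta.append((b, c, FREQUENCY, ""))
            if include_basal:
                blocks.append(med[b, :, c, :])
                col_meta.extend((b, c, BASAL, m) for m in func)
            blocks.append(resp[b, :, c, :])
            col_meta.extend((b, c, RESPONSE, m) for m in func)
    matrix = np.hstack(blocks)
    meta = pd.DataFrame(
        col_meta, columns=["iteration", "metacluster", "feature_type", "marker"]
    )
    columns = pd.MultiIndex.from_arrays(
        [
            meta["iteration"],
            meta["metacluster"],
            meta["feature_type"].str.cat(meta["marker"], sep="|").str.rstrip("|"),
        ],
        names=["iteration", "metacluster", "feature"],
    )
    features = pd.DataFrame(matrix, index=pd.Index(sids, name="sample_id"), columns=columns)
    return features, meta


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class BootstrapClusterModel:
    """Bootstrapped metaclustering of a :class:`Study`, statsmodels-style.

    Parameters
    ----------
    study:
        Arcsinh-scale study with population labels when neutrophil exclusion
        is requested.
    config:
        :class:`ClusterConfig`; defaults to the printed study parameters
        (K=30 metaclusters, B=200 iterations).
    """

    def __init__(self, study: Study, config: ClusterConfig | None = None):
        self.study = study
        self.config = config or ClusterConfig()

    def fit(self) -> "ClusterResults":
        cfg = self.config
        cfg.validate()
        study = self.study
        comp = study.population_compartments
        neutro = study.neutrophil_populations()

        local_labels: dict[str, np.ndarray] = {}
        centers_blocks = []
        provenance: list[tuple[str, int]] = []
        sids = study.sample_ids
        seeds = stage_seeds(cfg.seed, STAGE_SAMPLE_KMEANS, len(sids))
        dropped_total = 0
        for sid, seed in zip(sids, seeds):
            ct = study.samples[sid]
            if cfg.exclude_neutrophils and ct.labels is not None and neutro:
                incl = ~ct.labels.isin(neutro).to_numpy()
            else:
                incl = np.ones(ct.n_cells, dtype=bool)
            dropped_total += int((~incl).sum())
            X = ct.phenotypic_values()[incl]
            if X.shape[0] == 0:
                raise StateError(f"sample {sid!r} has no cells after neutrophil exclusion")
            k = cfg.k_rule(X.shape[0])
            centers, lab = cluster_sample(X, k, seed, n_init=cfg.n_init, tol=cfg.tol)
            full = np.full(ct.n_cells, -1, dtype=np.int32)
            full[incl] = lab
            local_labels[sid] = full
            centers_blocks.append(centers)
            provenance.extend((sid, j) for j in range(centers.shape[0]))
        log.info(
            "per-sample clustering done: %d samples, %d centers, %d neutrophil cells excluded",
            len(sids), sum(c.shape[0] for c in centers_blocks), dropped_total,
        )
        models = metacluster(np.vstack(centers_blocks), provenance, cfg)
        features, col_meta = build_cluster_features(
            study, models, local_labels, include_basal=cfg.include_basal
        )
        return ClusterResults(
            study=study,
            config=cfg,
            models=models,
            local_labels=local_labels,
            features=features,
            column_meta=col_meta,
        )


@dataclass
class ClusterResults:
    """Fitted metaclustering: models, per-cell labels, and the feature matrix."""

    study: Study
    config: ClusterConfig
    models: list[ClusterModel]
    local_labels: dict[str, np.ndarray]
    features: pd.DataFrame
    column_meta: pd.DataFrame
    _composition: pd.DataFrame | None = field(default=None, repr=False)

    # ---- feature selection ------------------------------------------------
    def features_for_timepoint(
        self, timepoint: str, mode: str | None = None
    ) -> tuple[pd.DataFrame, pd.Series]:
        """Feature matrix and arm labels for one timepoint's classifier.

        ``mode`` selects feature families (comma-joined from ``frequency``,
        ``basal``, ``response``). Defaults: ``frequency,basal`` at the
        baseline timepoint (responses are identically zero there) and
        ``frequency,response`` at post-baseline timepoints.
        """
        md = self.study.metadata
        rows = md.index[md["timepoint"] == timepoint]
        if len(rows) == 0:
            raise DesignError(f"no samples at timepoint {timepoint!r}")
        if mode is None:
            mode = (
                "frequency,basal"
                if timepoint == self.study.baseline_timepoint
                else "frequency,response"
            )
        wanted = {m.strip() for m in mode.split(",")}
        unknown = wanted - {FREQUENCY, BASAL, RESPONSE}
        if unknown:
            raise DesignError(f"unknown feature mode component(s): {sorted(unknown)}")
        mask = self.column_meta["feature_type"].isin(wanted).to_numpy()
        X = self.features.loc[rows, self.features.columns[mask]]
        y = md.loc[rows, "arm"]
        return X, y

    # ---- cell-level views -------------------------------------------------
    def cell_metacluster_labels(self, iteration: int) -> dict[str, np.ndarray]:
        return assign_cells(self.local_labels, self.models[iteration])

    def composition(self) -> pd.DataFrame:
        """Cells per (iteration, metacluster) x true population (included cells)."""
        if self._composition is None:
            frames = []
            for model in self.models:
                mc_labels = self.cell_metacluster_labels(model.iteration)
                labs, pops = [], []
                for sid in self.study.sample_ids:
                    ml = mc_labels[sid]
                    keep = ml >= 0
                    labs.append(ml[keep])
                    pops.append(self.study.samples[sid].labels.to_numpy()[keep])
                ct = pd.crosstab(
                    np.concatenate(labs), np.concatenate(pops)
                ).reindex(range(self.config.K), fill_value=0)
                ct.index = pd.MultiIndex.from_product(
                    [[model.iteration], ct.index], names=["iteration", "metacluster"]
                )
                frames.append(ct)
            self._composition = pd.concat(frames).fillna(0).astype(int)
        return self._composition

    def pooled_cluster_medians(self) -> pd.DataFrame:
        """Per (iteration, metacluster) median phenotypic expression of pooled cells."""
        phen_parts, lab_parts = [], []
        for sid in self.study.sample_ids:
            ct = self.study.samples[sid]
            keep = self.local_labels[sid] >= 0
            phen_parts.append(ct.phenotypic_values()[keep])
        phen = np.vstack(phen_parts)
        rows, idx = [], []
        K = self.config.K
        for model in self.models:
            mc_labels = self.cell_metacluster_labels(model.iteration)
            lab = np.concatenate(
                [mc_labels[sid][self.local_labels[sid] >= 0] for sid in self.study.sample_ids]
            )
            med = _grouped_medians(phen, lab, K)
            for c in range(K):
                if np.isfinite(med[c]).all():
                    rows.append(med[c])
                    idx.append((model.iteration, c))
        return pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(idx, names=["iteration", "metacluster"]),
            columns=list(self.study.panel.phenotypic),
        )

    # ---- bookkeeping ------------------------------------------------------
    def included_cell_count(self, sample_id: str) -> int:
        return int((self.local_labels[sample_id] >= 0).sum())

    def summary(self) -> str:
        cfg = self.config
        n_feat = self.features.shape[1]
        lines = [
            "Bootstrapped metaclustering results",
            "----------------------------------",
            f"samples:              {len(self.study.sample_ids)}",
            f"metaclusters (K):     {cfg.K}",
            f"iterations (B):       {cfg.B}",
            f"feature groups (B*K): {cfg.B * cfg.K}",
            f"feature columns:      {n_feat}",
            f"neutrophil exclusion: {cfg.exclude_neutrophils}",
        ]
        return "\n".join(lines)

    # ---- persistence ------------------------------------------------------
    def save_features(self, features_path, meta_path) -> None:
        flat = self.features.copy()
        flat.columns = [f"{b}|{c}|{f}" for b, c, f in self.features.columns]
        flat.to_csv(features_path)
        self.column_meta.to_csv(meta_path, index=False)

    def save_centroids(self, path) -> None:
        frames = []
        for model in self.models:
            df = pd.DataFrame(model.centroids, columns=list(self.study.panel.phenotypic))
            df.insert(0, "metacluster", range(df.shape[0]))
            df.insert(0, "iteration", model.iteration)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
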