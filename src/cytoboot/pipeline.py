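"""Pipeline orchestration: simulate -> features -> cluster -> classify -> atlas -> trajectory.

Every stage writes its artifacts under one output directory; an
``artifacts.json`` manifest records SHA-256 hashes so reruns with the same
master seed can be verified bit-for-bit for the deterministic stages. One
master seed deterministically derives all stage seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import yaml

from ._utils import derive_seed
from .clustering import BootstrapClusterModel, ClusterConfig
from .classify import TimepointClassifier
from .data import assemble_study, write_study
from .errors import ConfigurationError, StateError
from .features import export_features, population_frequencies, population_signaling
from .simulate import StudyConfig, generate_study, small_config, treatment_like_effects
from .trajectories import DEFAULT_N_NEIGHBORS, ImmuneTrajectoryModel

log = logging.getLogger(__name__)

STAGES = ("simulate", "features", "cluster", "classify", "atlas", "trajectory")


@dataclass
class PipelineConfig:
    """Master configuration; one seed derives every stage seed."""

    study: StudyConfig = field(default_factory=small_config)
    cluster_K: int = 30
    cluster_B: int = 200
    exclude_neutrophils: bool = True
    classifier_iterations: int = 200
    classifier_trees: int = 500
    trajectory_neighbors: int = DEFAULT_N_NEIGHBORS
    seed: int = 0

    def __post_init__(self):
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")

    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(
            K=self.cluster_K,
            B=self.cluster_B,
            exclude_neutrophils=self.exclude_neutrophils,
            seed=derive_seed(self.seed, 10),
        )

    # YAML round trip (callables and panels re-derived from defaults)
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["study"] = {
            k: v
            for k, v in dataclasses.asdict(self.study).items()
            if k in ("n_patients_per_arm", "arms", "timepoints", "cells_per_sample", "seed")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        study_kw = d.pop("study", {}) or {}
        for key in ("arms", "timepoints"):
            if key in study_kw and study_kw[key] is not None:
                study_kw[key] = tuple(study_kw[key])
        if isinstance(study_kw.get("n_patients_per_arm"), list):
            study_kw["n_patients_per_arm"] = tuple(study_kw["n_patients_per_arm"])
        if isinstance(study_kw.get("cells_per_sample"), list):
            study_kw["cells_per_sample"] = tuple(study_kw["cells_per_sample"])
        return cls(study=StudyConfig(**study_kw), **d)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def demo_config(seed: int = 0) -> PipelineConfig:
    """Reduced-scale planted-effect walkthrough (B=20, K=10)."""
    study = small_config(
        seed=derive_seed(seed, 1),
        effects=treatment_like_effects(timepoints=("1h", "6h")),
    )
    return PipelineConfig(
        study=study,
        cluster_K=10,
        cluster_B=20,
        classifier_iterations=50,
        classifier_trees=100,
        seed=seed,
    )


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
    outdir: str = "cytoboot_out",
) -> dict[str, str]:
    """Run the requested stages; returns {artifact name: path}.

    Earlier stages' outputs are consumed in-memory when produced in the same
    call, otherwise re-read from ``outdir``. A missing upstream artifact
    raises a :class:`StateError` naming the stage to run first.
    """
    for st in stages:
        if st not in STAGES:
            raise ConfigurationError(f"unknown stage {st!r}; valid: {STAGES}")
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cytoboot")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    artifacts: dict[str, str] = {}
    study = None
    cluster_results = None
    t0 = time.time()
    try:
        log.info("pipeline start: stages=%s seed=%d outdir=%s", stages, config.seed, outdir)
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        artifacts["config"] = os.path.join(outdir, "config.yaml")

        if "simulate" in stages:
            t = time.time()
            study = generate_study(config.study)
            study_dir = os.path.join(outdir, "study")
            artifacts["manifest"] = write_study(study, study_dir)
            log.info("simulate: %d samples in %.1fs", len(study.sample_ids), time.time() - t)

        def _study():
            nonlocal study
            if study is None:
                manifest = os.path.join(outdir, "study", "manifest.csv")
                if not os.path.exists(manifest):
                    raise StateError("no study on disk; run 'simulate' first")
                study = assemble_study(
                    manifest,
                    config.study.panel,
                    timepoint_order=config.study.timepoints,
                    population_compartments=config.study.compartments(),
                )
            return study

        if "features" in stages:
            t = time.time()
            st = _study()
            freq = population_frequencies(st)
            basal, resp = population_signaling(st)
            path = os.path.join(outdir, "population_features.csv")
            export_features(freq, basal, resp, path)
            artifacts["population_features"] = path
            log.info("features: wrote %s in %.1fs", path, time.time() - t)

        if "cluster" in stages:
            t = time.time()
            cluster_results = BootstrapClusterModel(_study(), config.cluster_config()).fit()
            fpath = os.path.join(outdir, "cluster_features.csv")
            mpath = os.path.join(outdir, "cluster_feature_columns.csv")
            cpath = os.path.join(outdir, "cluster_centroids.csv")
            cluster_results.save_features(fpath, mpath)
            cluster_results.save_centroids(cpath)
            artifacts.update(
                cluster_features=fpath, cluster_feature_columns=mpath, cluster_centroids=cpath
            )
            log.info("cluster: B=%d K=%d in %.1fs", config.cluster_B, config.cluster_K, time.time() - t)

        if "classify" in stages:
            if cluster_results is None:
                raise StateError("classify needs cluster features; run 'cluster' first")
            st = _study()
            for tp in st.timepoint_order:
                t = time.time()
                X, y = cluster_results.features_for_timepoint(tp)
                result = TimepointClassifier(
                    X, y,
                    timepoint=tp,
                    n_iter=config.classifier_iterations,
                    n_estimators=config.classifier_trees,
                    seed=derive_seed(config.seed, 20 + list(st.timepoint_order).index(tp)),
                ).fit()
                path = os.path.join(outdir, f"classifier_{tp}.json")
                result.save_json(path)
                artifacts[f"classifier_{tp}"] = path
                log.info(
                    "classify %s: AUC=%.3f p=%.3g in %.1fs",
                    tp, result.auc, result.p_value, time.time() - t,
                )

        if "atlas" in stages:
            if cluster_results is None:
                raise StateError("atlas needs cluster features; run 'cluster' first")
            from .atlas import ImmuneAtlas  # local import keeps matplotlib optional at import time

            t = time.time()
            st = _study()
            atlas_result = ImmuneAtlas(cluster_results).fit()
            coords_path = os.path.join(outdir, "atlas_coordinates.csv")
            atlas_result.coordinates.coords.to_csv(coords_path)
            artifacts["atlas_coordinates"] = coords_path
            for tp in st.timepoint_order[1:]:
                stats = atlas_result.group_stats(tp)
                spath = os.path.join(outdir, f"atlas_stats_{tp}.csv")
                stats.save_csv(spath)
                artifacts[f"atlas_stats_{tp}"] = spath
                ppath = os.path.join(outdir, f"atlas_best_p_{tp}.png")
                atlas_result.plot(stats, "best_p", path=ppath)
                artifacts[f"atlas_best_p_{tp}"] = ppath
            log.info("atlas: %d clusters in %.1fs", len(atlas_result.coordinates.coords), time.time() - t)

        if "trajectory" in stages:
            t = time.time()
            st = _study()
            traj = ImmuneTrajectoryModel(st, n_neighbors=config.trajectory_neighbors).fit()
            epath = os.path.join(outdir, "trajectory_embedding.csv")
            traj.save_csv(epath)
            artifacts["trajectory_embedding"] = epath
            ppath = os.path.join(outdir, "trajectories.png")
            traj.plot(path=ppath)
            artifacts["trajectories_plot"] = ppath
            log.info("trajectory: %d points in %.1fs", len(traj.embedding), time.time() - t)

        hashes = {name: _sha256(path) for name, path in artifacts.items() if os.path.isfile(path)}
        with open(os.path.join(outdir, "artifacts.json"), "w") as fh:
            json.dump({"artifacts": artifacts, "sha256": hashes, "seed": config.seed}, fh, indent=2)
        log.info("pipeline done in %.1fs", time.time() - t0)
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts
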