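"""Config-driven end-to-end runner, one stratum (cohort dialect x sex) at a time.

Stages per stratum: synthetic cohort generation -> silhouette-based k
selection -> k-means fit -> cluster profiling and rule-based labeling ->
incidence / disease-count tables -> nested-CV random-forest
classification -> within-CV Shapley explanation -> CSV/JSON export.
Every stage is seeded from the single run seed, so a rerun with the same
configuration reproduces every output byte for byte (the manifest's
wall-clock timings aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVConfig, run_nested_cv
from .clustering import fit_clusters, label_clusters, profile_clusters, select_k
from .explain import compute_shap_cv, directionality_summary, global_importance
from .labels import PatternLabel
from .simulate import STRATA, generate_cohort, stratum_config
from .stats import disease_count_summary, incidence_table
from .trajectory import frame_to_trajectories

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)

#: Covariate-table columns that are identifiers/outcome plumbing, not predictors.
_NON_PREDICTORS = ("participant_id", "sex", "follow_up_years")


@dataclass(frozen=True)
class PipelineConfig:
    """Run settings; `quick` selects the reduced CV profile for smoke runs."""

    seed: int = 0
    outdir: str = "cmc_run"
    strata: tuple = tuple(STRATA)
    n: Optional[int] = None  # per-stratum size; None = reference size
    quick: bool = False
    missingness_rate: float = 0.03
    k_range: tuple[int, int] = (2, 8)
    shap_top_m: int = 10

    def cv_config(self, seed: int) -> CVConfig:
        return CVConfig.quick(seed=seed) if self.quick else CVConfig(seed=seed)


@dataclass
class RunManifest:
    """What a run produced: config hash, seed, timings, outputs, version."""

    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    completed: bool = False

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "completed": self.completed,
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; unknown keys raise with their path."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "seed", "outdir", "strata", "n", "quick", "missingness_rate",
        "k_range", "shap_top_m",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)} in {path}")
    if "strata" in raw:
        raw["strata"] = tuple(tuple(s) for s in raw["strata"])
    if "k_range" in raw:
        raw["k_range"] = tuple(raw["k_range"])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: list(v) if isinstance(v, tuple) else v for k, v in vars(config).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, outputs: list) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    outputs.append(str(path))


def _write_json(obj, path: Path, outputs: list) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append(str(path))


def _stage(manifest: RunManifest, name: str, t0: float) -> None:
    manifest.stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})


def _stratum_seed(seed: int, dialect: str, sex: str) -> int:
    h = hashlib.sha256(f"{seed}:{dialect}:{sex}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def simulate_stage(config: PipelineConfig, dialect: str, sex: str, outdir: Path,
                   outputs: list):
    """Generate and persist one synthetic stratum."""
    seed = _stratum_seed(config.seed, dialect, sex)
    scfg = stratum_config(
        dialect, sex, n=config.n, seed=seed, missingness_rate=config.missingness_rate
    )
    cov, traj, truth = generate_cohort(scfg)
    _write_csv(cov, outdir / "covariates.csv", outputs)
    _write_csv(traj, outdir / "trajectories.csv", outputs)
    _write_csv(truth.to_frame(), outdir / "true_labels.csv", outputs)
    return cov, traj, truth, seed


def cluster_stage(config: PipelineConfig, traj: pd.DataFrame, seed: int,
                  outdir: Path, outputs: list, manifest_warnings: list):
    """Select k, fit, profile and label clusters; export the table analogues."""
    trajectories = frame_to_trajectories(traj)
    lo, hi = config.k_range
    k_star, sil_table = select_k(traj, range(lo, hi + 1), seed=seed)
    model = fit_clusters(traj, k_star, seed=seed)
    profiles = profile_clusters(model, trajectories)
    labels = label_clusters(profiles, trajectories, assignments=model.assignments)
    if any(lab == PatternLabel.UNLABELED.value for lab in labels.values()):
        manifest_warnings.append(f"unlabeled cluster(s): {labels}")
    _write_csv(sil_table, outdir / "silhouette_by_k.csv", outputs)

    prof_rows, pattern_rows = [], []
    for p in profiles:
        row = {"cluster": p.cluster, "label": labels[p.cluster], "n": p.n}
        for dis in ("HYP", "DM", "HD", "STK"):
            row[f"{dis}_incidence_pct"] = p.incidence_pct[dis]
            row[f"{dis}_mean_time"] = p.mean_time[dis]
            row[f"{dis}_sd_time"] = p.sd_time[dis]
        prof_rows.append(row)
        top = p.pattern_counts.head(5).copy()
        top.insert(0, "cluster", p.cluster)
        top.insert(1, "label", labels[p.cluster])
        pattern_rows.append(top)
    _write_csv(pd.DataFrame(prof_rows), outdir / "cluster_profiles.csv", outputs)
    _write_csv(pd.concat(pattern_rows, ignore_index=True),
               outdir / "cluster_patterns.csv", outputs)

    per_participant = pd.Series(
        [labels[a] for a in model.assignments], name="pattern"
    )
    _write_csv(per_participant.to_frame(), outdir / "cluster_assignments.csv", outputs)
    return model, profiles, labels, per_participant


def stats_stage(traj: pd.DataFrame, pattern: pd.Series, outdir: Path, outputs: list):
    """Incidence/timing and disease-count summaries (Table-1 analogues)."""
    trajectories = frame_to_trajectories(traj)
    rows = []
    for summ in incidence_table(trajectories, ["all"] * len(trajectories)) + \
            incidence_table(trajectories, list(pattern)):
        for dis in ("HYP", "DM", "HD", "STK"):
            rows.append({
                "group": summ.group, "n": summ.n, "disease": dis,
                "count": summ.count[dis],
                "incidence_pct": summ.incidence_pct[dis],
                "mean_time": summ.mean_time[dis],
                "sd_time": summ.sd_time[dis],
            })
    _write_csv(pd.DataFrame(rows), outdir / "incidence.csv", outputs)
    _write_csv(disease_count_summary(trajectories), outdir / "disease_counts.csv", outputs)


def classify_stage(config: PipelineConfig, cov: pd.DataFrame, pattern: pd.Series,
                   seed: int, outdir: Path, outputs: list):
    """Nested-CV random forest on baseline covariates vs cluster patterns."""
    predictors = cov.drop(columns=[c for c in _NON_PREDICTORS if c in cov.columns])
    metrics, folds = run_nested_cv(predictors, pattern, config.cv_config(seed))
    _write_json(
        {"mean": metrics.mean, "sd": metrics.sd}, outdir / "metrics.json", outputs
    )
    _write_csv(metrics.per_fold, outdir / "metrics_per_fold.csv", outputs)
    return metrics, folds


def explain_stage(config: PipelineConfig, folds, outdir: Path, outputs: list):
    """Within-CV Shapley attributions -> global ranking + directionality data."""
    shap_result = compute_shap_cv(folds)
    glob_rows, direction_rows = [], []
    for cls in shap_result.classes:
        top = global_importance(shap_result, cls, top_m=config.shap_top_m)
        top.insert(0, "class", cls)
        glob_rows.append(top)
        for feat in top["feature"].head(3):
            table, score = directionality_summary(shap_result, feat, cls)
            direction_rows.append({
                "class": cls, "feature": feat,
                "sign_concordance": score,
                "mean_shap_high_value": float(
                    table.loc[table["value"] > table["value"].median(), "shap"].mean()
                ) if table["value"].nunique() > 1 else float("nan"),
            })
    _write_csv(pd.concat(glob_rows, ignore_index=True),
               outdir / "shap_global_importance.csv", outputs)
    _write_csv(pd.DataFrame(direction_rows), outdir / "shap_directionality.csv", outputs)
    return shap_result


def run_pipeline(config: PipelineConfig | str | os.PathLike) -> RunManifest:
    """Run every stage for every configured stratum; returns the manifest.

    The manifest (written atomically to ``<outdir>/manifest.json``)
    records the config hash, per-stage timings, warnings and the full
    output inventory; on a stage failure it is still written with
    ``completed: false`` and whatever stages finished.
    """
    if not isinstance(config, PipelineConfig):
        config = load_pipeline_config(config)
    outroot = Path(config.outdir)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, version=__version__
    )
    try:
        for dialect, sex in config.strata:
            sdir = outroot / f"{dialect}_{sex}"
            t0 = time.time()
            cov, traj, truth, seed = simulate_stage(
                config, dialect, sex, sdir, manifest.outputs
            )
            _stage(manifest, f"simulate[{dialect},{sex}]", t0)

            t0 = time.time()
            model, profiles, labels, pattern = cluster_stage(
                config, traj, seed, sdir, manifest.outputs, manifest.warnings
            )
            _stage(manifest, f"cluster[{dialect},{sex}] k={model.k}", t0)

            t0 = time.time()
            stats_stage(traj, pattern, sdir, manifest.outputs)
            _stage(manifest, f"stats[{dialect},{sex}]", t0)

            t0 = time.time()
            metrics, folds = classify_stage(
                config, cov, pattern, seed, sdir, manifest.outputs
            )
            _stage(manifest, f"classify[{dialect},{sex}]", t0)

            t0 = time.time()
            explain_stage(config, folds, sdir, manifest.outputs)
            _stage(manifest, f"explain[{dialect},{sex}]", t0)
        manifest.completed = True
    finally:
        _write_manifest(manifest, outroot)
    return manifest


def _write_manifest(manifest: RunManifest, outroot: Path) -> None:
    outroot.mkdir(parents=True, exist_ok=True)
    tmp = outroot / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, outroot / "manifest.json")
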