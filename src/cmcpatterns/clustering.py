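"""Pattern discovery: k-means on 4-tuple trajectories with silhouette k selection.

Trajectories are clustered on the raw fractional-time 4-tuples — no
scaling is applied because all four coordinates already live on the same
(0, 1] scale.  The number of clusters is chosen by maximising the mean
silhouette coefficient, each cluster is profiled (incidence, timing and
ordered-pattern frequencies) and profiles are mapped to named patterns
by precedence-ordered rules on the first disease, its onset window, and
the disease-free fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .labels import PatternLabel
from .trajectory import (
    ARROW,
    NO_DISEASE_PATTERN,
    DiseaseCode,
    N_DISEASES,
    Trajectory,
    first_disease,
    pattern_string,
    time_matrix,
)

__all__ = [
    "ClusterModel",
    "ClusterProfile",
    "LabelRuleConfig",
    "fit_clusters",
    "select_k",
    "profile_clusters",
    "label_clusters",
    "LOW_SEPARATION_THRESHOLD",
    "SILHOUETTE_SUBSAMPLE",
]

logger = logging.getLogger(__name__)

#: Mean silhouette below which select_k warns of weak cluster separation.
LOW_SEPARATION_THRESHOLD = 0.25

#: Above this sample size the silhouette is computed on a seeded uniform
#: subsample (a performance convention; the score is an average anyway).
SILHOUETTE_SUBSAMPLE = 20_000


@dataclass
class ClusterModel:
    """A fitted k-means partition of the trajectory 4-tuples."""

    k: int
    centroids: np.ndarray  # (k, 4)
    assignments: np.ndarray  # (n,)
    inertia: float
    seed: int
    n_init: int

    def __post_init__(self) -> None:
        if self.assignments.min(initial=0) < 0 or self.assignments.max(initial=0) >= self.k:
            raise ValueError("assignments outside [0, k)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid")


@dataclass
class ClusterProfile:
    """Per-cluster incidence, timing and ordered-pattern summary."""

    cluster: int
    n: int
    incidence_pct: dict[str, float]  # per disease, 0..100
    mean_time: dict[str, Optional[float]]  # mean t_i among occurred, None if none
    sd_time: dict[str, Optional[float]]
    first_disease_pct: dict[str, float]  # includes "None"
    pattern_counts: pd.DataFrame  # columns: pattern, count, pct (desc by count)

    @property
    def none_disease_pct(self) -> float:
        row = self.pattern_counts[self.pattern_counts["pattern"] == NO_DISEASE_PATTERN]
        return float(row["pct"].iloc[0]) if len(row) else 0.0


def fit_clusters(
    trajectories,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Lloyd's k-means on raw 4-tuples, best of ``n_init`` seeded restarts.

    ``trajectories`` may be a sequence of :class:`Trajectory`, a tabular
    trajectory frame, or an (n, 4) array of fractional times.
    """
    X = _as_matrix(trajectories)
    if len(X) == 0:
        raise ValueError("no trajectories to cluster")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct 4-tuples for k = {k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
    )


def select_k(
    trajectories,
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by the average-silhouette method.

    Fits k-means for every k in ``k_range`` and returns the k with the
    highest mean silhouette coefficient (Euclidean), together with the
    full per-k score table for diagnostics.  A low-separation warning is
    logged when even the best score falls below
    :data:`LOW_SEPARATION_THRESHOLD`.
    """
    X = _as_matrix(trajectories)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 trajectories to select k")
    k_range = [int(k) for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    sil_kwargs = {}
    if n > SILHOUETTE_SUBSAMPLE:
        sil_kwargs = {"sample_size": SILHOUETTE_SUBSAMPLE, "random_state": seed}

    rows = []
    for k in k_range:
        model = fit_clusters(X, k, seed=seed, n_init=n_init)
        if len(np.unique(model.assignments)) < 2:
            score = float("nan")
        else:
            score = float(silhouette_score(X, model.assignments, **sil_kwargs))
        rows.append({"k": k, "mean_silhouette": score, "inertia": model.inertia})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_silhouette"].idxmax()]
    k_star = int(best["k"])
    if best["mean_silhouette"] < LOW_SEPARATION_THRESHOLD:
        warnings.warn(
            f"weak cluster separation: best mean silhouette "
            f"{best['mean_silhouette']:.3f} < {LOW_SEPARATION_THRESHOLD} at k={k_star}",
            stacklevel=2,
        )
    return k_star, table


def profile_clusters(model: ClusterModel, trajectories) -> list[ClusterProfile]:
    """Summarise each cluster: incidence, timing and ordered patterns.

    Incidence is the percentage of cluster members with the disease;
    mean/sd of the fractional onset time are computed over occurred
    members only (reported as None for a disease nobody in the cluster
    developed); the ordered-pattern table counts every distinct
    arrow-joined trajectory string, descending.
    """
    trajs = _as_trajectories(trajectories)
    if len(trajs) != len(model.assignments):
        raise ValueError("assignments do not cover the trajectories")
    profiles = []
    for c in range(model.k):
        members = [t for t, a in zip(trajs, model.assignments) if a == c]
        n = len(members)
        incidence, mean_t, sd_t = {}, {}, {}
        for d in DiseaseCode:
            occ_times = [t.times[d] for t in members if t.occurred[d]]
            incidence[d.label] = 100.0 * len(occ_times) / n if n else 0.0
            if occ_times:
                mean_t[d.label] = float(np.mean(occ_times))
                sd_t[d.label] = float(np.std(occ_times, ddof=1)) if len(occ_times) > 1 else 0.0
            else:
                mean_t[d.label] = None
                sd_t[d.label] = None
        firsts = [first_disease(t)[0] for t in members]
        first_pct = {
            d.label: 100.0 * sum(f == d for f in firsts) / n if n else 0.0
            for d in DiseaseCode
        }
        first_pct["None"] = 100.0 * sum(f is None for f in firsts) / n if n else 0.0
        patterns = pd.Series([pattern_string(t) for t in members], dtype=str)
        counts = patterns.value_counts()
        pattern_counts = pd.DataFrame(
            {
                "pattern": counts.index,
                "count": counts.to_numpy(),
                "pct": 100.0 * counts.to_numpy() / n if n else 0.0,
            }
        ).reset_index(drop=True)
        profiles.append(
            ClusterProfile(
                cluster=c, n=n, incidence_pct=incidence,
                mean_time=mean_t, sd_time=sd_t,
                first_disease_pct=first_pct, pattern_counts=pattern_counts,
            )
        )
    return profiles


@dataclass(frozen=True)
class LabelRuleConfig:
    """Thresholds for the precedence-ordered labeling rules.

    Defaults are the weakest bounds reported across the four reference
    strata, so that every reference scenario satisfies its rule:

    * Healthy: disease-free fraction >= 88%;
    * FirstHD: all members have heart disease, HD first for >= 75%;
    * FirstDM: all members have diabetes, DM first for >= 78%;
    * EarlyHyp: all members have hypertension, HYP first for >= 92%,
      and >= 95% of HYP onsets within 40% of follow-up;
    * LateHyp: as EarlyHyp but onsets in 40–80% of follow-up.
    """

    healthy_none_pct: float = 88.0
    first_hd_first_pct: float = 75.0
    first_dm_first_pct: float = 78.0
    hyp_first_pct: float = 92.0
    hyp_window_pct: float = 95.0
    early_hyp_window: tuple[float, float] = (0.0, 0.4)
    late_hyp_window: tuple[float, float] = (0.4, 0.8)
    incidence_all_pct: float = 100.0


def _hyp_times_within(members, lo, hi) -> float:
    times = [t.times[DiseaseCode.HYP] for t in members if t.occurred[DiseaseCode.HYP]]
    if not times:
        return 0.0
    return 100.0 * sum(lo < x <= hi for x in times) / len(times)


def label_clusters(
    profiles: Sequence[ClusterProfile],
    trajectories,
    assignments: Optional[np.ndarray] = None,
    rule_config: LabelRuleConfig = LabelRuleConfig(),
) -> dict[int, str]:
    """Map each cluster to a named pattern by precedence-ordered rules.

    Rules are evaluated Healthy → FirstHD → FirstDM → EarlyHyp → LateHyp;
    the first match wins and an unmatched cluster is ``Unlabeled``.  If
    two clusters earn the same substantive label both are kept with
    ``#2``-style suffixes and a warning is emitted.

    ``trajectories``/``assignments`` supply the member-level HYP onset
    times needed by the EarlyHyp/LateHyp window conditions; assignments
    default to cluster order of ``profiles`` applied to the model that
    produced them.
    """
    if not profiles:
        raise ValueError("no cluster profiles to label")
    trajs = _as_trajectories(trajectories)
    if assignments is None:
        raise ValueError("assignments are required to evaluate window rules")
    members_by_cluster = {
        p.cluster: [t for t, a in zip(trajs, assignments) if a == p.cluster]
        for p in profiles
    }
    rc = rule_config
    labels: dict[int, str] = {}
    for p in profiles:
        members = members_by_cluster[p.cluster]
        hyp_inc = p.incidence_pct["HYP"]
        label = PatternLabel.UNLABELED.value
        if p.none_disease_pct >= rc.healthy_none_pct:
            label = PatternLabel.HEALTHY.value
        elif (
            p.incidence_pct["HD"] >= rc.incidence_all_pct
            and p.first_disease_pct["HD"] >= rc.first_hd_first_pct
        ):
            label = PatternLabel.FIRST_HD.value
        elif (
            p.incidence_pct["DM"] >= rc.incidence_all_pct
            and p.first_disease_pct["DM"] >= rc.first_dm_first_pct
        ):
            label = PatternLabel.FIRST_DM.value
        elif (
            hyp_inc >= rc.incidence_all_pct
            and p.first_disease_pct["HYP"] >= rc.hyp_first_pct
            and _hyp_times_within(members, *rc.early_hyp_window) >= rc.hyp_window_pct
        ):
            label = PatternLabel.EARLY_HYP.value
        elif (
            hyp_inc >= rc.incidence_all_pct
            and p.first_disease_pct["HYP"] >= rc.hyp_first_pct
            and _hyp_times_within(members, *rc.late_hyp_window) >= rc.hyp_window_pct
        ):
            label = PatternLabel.LATE_HYP.value
        labels[p.cluster] = label

    # duplicate substantive labels: keep both, suffixed, and warn
    seen: dict[str, list[int]] = {}
    for c, lab in labels.items():
        if lab != PatternLabel.UNLABELED.value:
            seen.setdefault(lab, []).append(c)
    for lab, clusters in seen.items():
        if len(clusters) > 1:
            warnings.warn(
                f"label {lab!r} matched clusters {clusters}; keeping both with suffixes",
                stacklevel=2,
            )
            for i, c in enumerate(clusters[1:], start=2):
                labels[c] = f"{lab}#{i}"
    return labels


# ---------------------------------------------------------------------------


def _as_matrix(trajectories) -> np.ndarray:
    if isinstance(trajectories, np.ndarray):
        X = np.asarray(trajectories, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_DISEASES:
            raise ValueError(f"expected (n, {N_DISEASES}) array, got {X.shape}")
        return X
    return time_matrix(trajectories)


def _as_trajectories(trajectories) -> list[Trajectory]:
    if isinstance(trajectories, pd.DataFrame):
        from .trajectory import frame_to_trajectories

        return frame_to_trajectories(trajectories)
    return list(trajectories)
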