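"""Seeded synthetic cohorts with latent cardiometabolic-continuum patterns.

Real multi-disease cohorts of this kind (UK Biobank, ELSA-Brasil) are
access-restricted, so the package ships a generative stand-in that
reproduces the *structure* the analysis assumes:

* five latent temporal patterns (EarlyHyp, LateHyp, FirstDM, FirstHD,
  Healthy) with severe class imbalance — the Healthy share ranges from
  roughly two thirds to over nine tenths depending on stratum;
* within each pattern, the designated first disease's fractional onset
  time drawn from a pattern-specific window, with optional later
  secondary diseases at strictly later times;
* baseline covariates in two cohort "dialects" (``uk`` and ``elsa``)
  whose values can shift pattern-membership log-odds; and
* MCAR missingness injected into covariates only.

Everything is driven by a single integer seed through independent
substreams (covariates, membership, event times), so any stage can be
re-run reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .labels import CORE_LABELS, PatternLabel
from .trajectory import DiseaseCode, N_DISEASES, Trajectory, trajectories_to_frame

__all__ = [
    "PatternSpec",
    "CovariateSpec",
    "SyntheticConfig",
    "generate_cohort",
    "inject_missingness",
    "stratum_config",
    "load_config",
    "save_config",
    "STRATA",
]

STRATA = [("uk", "male"), ("uk", "female"), ("elsa", "male"), ("elsa", "female")]


class ConfigError(ValueError):
    """Raised for an internally inconsistent generator configuration."""


@dataclass(frozen=True)
class PatternSpec:
    """Generative description of one latent pattern.

    ``first_disease`` is None for the Healthy pattern; then
    ``first_time_window`` is the window used for any (rare, isolated)
    disease the pattern does produce.  ``incidence`` holds per-disease
    occurrence probabilities in canonical order; for a pattern with a
    designated first disease that disease's entry must be 1.  Secondary
    diseases occur at a time drawn uniformly between the first onset and
    the end of follow-up.
    """

    label: PatternLabel
    mixing_proportion: float
    incidence: tuple[float, float, float, float]
    first_disease: Optional[DiseaseCode]
    first_time_window: tuple[float, float]
    #: A secondary disease occurs at t1 + u * (1 - t1) with u drawn
    #: uniformly from this interval: late in the residual follow-up, so
    #: that members with and without secondaries stay one coherent blob.
    secondary_delay_frac: tuple[float, float] = (0.6, 1.0)

    def validate(self) -> None:
        lo, hi = self.first_time_window
        if not (0 <= lo < hi <= 1):
            raise ConfigError(
                f"{self.label}: time window ({lo}, {hi}] must lie within (0, 1]"
            )
        if len(self.incidence) != N_DISEASES:
            raise ConfigError(f"{self.label}: incidence needs {N_DISEASES} entries")
        if any(not (0 <= p <= 1) for p in self.incidence):
            raise ConfigError(f"{self.label}: incidences must be probabilities")
        if self.first_disease is not None and self.incidence[self.first_disease] != 1.0:
            raise ConfigError(
                f"{self.label}: designated first disease must have incidence 1"
            )
        dlo, dhi = self.secondary_delay_frac
        if not (0 <= dlo < dhi <= 1):
            raise ConfigError(f"{self.label}: secondary_delay_frac must nest in [0, 1]")


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate and its effect on pattern membership.

    Continuous covariates are Gaussian(mean, sd); their effect is an
    additive shift of the pattern's membership log-odds per standard
    deviation.  Categorical covariates carry per-level shifts.  Effects
    are centred (expected shift subtracted) so that the marginal pattern
    frequencies stay close to the mixing proportions.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    levels: Optional[tuple[str, ...]] = None
    probs: Optional[tuple[float, ...]] = None
    mean: float = 0.0
    sd: float = 1.0
    effects: Mapping[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ConfigError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise ConfigError(f"{self.name}: categorical needs >= 2 levels")
            if self.probs is not None and len(self.probs) != len(self.levels):
                raise ConfigError(f"{self.name}: probs/levels length mismatch")
        else:
            if self.sd <= 0:
                raise ConfigError(f"{self.name}: sd must be positive")
        for lab, eff in self.effects.items():
            vals = eff.values() if isinstance(eff, Mapping) else [eff]
            if any(not np.isfinite(float(v)) for v in vals):
                raise ConfigError(f"{self.name}: non-finite effect for {lab}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of one synthetic stratum."""

    n: int
    cohort_dialect: str
    sex: str
    seed: int
    pattern_specs: tuple[PatternSpec, ...]
    covariate_specs: tuple[CovariateSpec, ...]
    missingness_rate: float = 0.0
    follow_up_mean: float = 11.0
    follow_up_sd: float = 0.6

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        if not (0 <= self.missingness_rate <= 1):
            raise ConfigError("missingness_rate must lie in [0, 1]")
        total = sum(p.mixing_proportion for p in self.pattern_specs)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixing proportions sum to {total}, expected 1")
        for p in self.pattern_specs:
            p.validate()
        for c in self.covariate_specs:
            c.validate()


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _substreams(seed: int, n_streams: int) -> list[np.random.Generator]:
    """Derive independent per-stage generators from one config seed."""
    children = np.random.SeedSequence(seed).spawn(n_streams)
    return [np.random.default_rng(c) for c in children]


def _draw_covariates(specs, n, rng) -> pd.DataFrame:
    cols: dict = {}
    for spec in specs:
        if spec.kind == "continuous":
            cols[spec.name] = rng.normal(spec.mean, spec.sd, size=n)
        else:
            probs = spec.probs
            if probs is None:
                probs = tuple(1.0 / len(spec.levels) for _ in spec.levels)
            idx = rng.choice(len(spec.levels), size=n, p=np.asarray(probs) / np.sum(probs))
            cols[spec.name] = pd.Categorical.from_codes(idx, categories=list(spec.levels))
    return pd.DataFrame(cols)


def _membership_logits(config: SyntheticConfig, cov: pd.DataFrame) -> np.ndarray:
    """Per-row membership log-odds: log mixing proportion + centred effects."""
    n = len(cov)
    labels = [p.label.value for p in config.pattern_specs]
    base = np.log([max(p.mixing_proportion, 1e-12) for p in config.pattern_specs])
    logits = np.tile(base, (n, 1))
    for spec in config.covariate_specs:
        for j, lab in enumerate(labels):
            eff = spec.effects.get(lab)
            if eff is None:
                continue
            if spec.kind == "continuous":
                z = (cov[spec.name].to_numpy(float) - spec.mean) / spec.sd
                logits[:, j] += float(eff) * z
            else:
                shifts = np.array(
                    [float(eff.get(lev, 0.0)) for lev in spec.levels]
                )
                probs = spec.probs
                if probs is None:
                    probs = np.full(len(spec.levels), 1.0 / len(spec.levels))
                centred = shifts - float(np.dot(probs, shifts))
                codes = cov[spec.name].cat.codes.to_numpy()
                logits[:, j] += centred[codes]
    return logits


def _draw_membership(logits: np.ndarray, rng) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(p))[:, None]
    return (u > cum).sum(axis=1)


def _draw_trajectory_times(spec: PatternSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw (times, occurred) for one participant of this pattern."""
    times = np.ones(N_DISEASES)
    occurred = np.zeros(N_DISEASES, dtype=bool)
    lo, hi = spec.first_time_window
    if spec.first_disease is not None:
        first = int(spec.first_disease)
        t1 = rng.uniform(lo, hi)
        times[first] = t1
        occurred[first] = True
        for d in range(N_DISEASES):
            if d == first:
                continue
            if rng.random() < spec.incidence[d]:
                # secondary disease strictly later on the continuum
                dlo, dhi = spec.secondary_delay_frac
                times[d] = t1 + rng.uniform(dlo, dhi) * (1.0 - t1)
                occurred[d] = True
    else:
        for d in range(N_DISEASES):
            if rng.random() < spec.incidence[d]:
                times[d] = rng.uniform(lo, hi)
                occurred[d] = True
    # an exact 1.0 draw would be indistinguishable from absence
    times[occurred] = np.minimum(times[occurred], 1.0 - 1e-9)
    return times, occurred


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate one synthetic stratum.

    Returns
    -------
    covariates : DataFrame
        One row per participant: ``participant_id``, ``sex``,
        ``follow_up_years`` and the dialect's baseline covariates, with
        MCAR missingness already injected at ``config.missingness_rate``.
    trajectories : DataFrame
        Encoded 4-tuples in the tabular dialect of
        :func:`cmcpatterns.trajectory.trajectories_to_frame`.
    labels : Series
        The planted (true) pattern label per participant.
    """
    config.validate()
    n = config.n
    rng_cov, rng_mem, rng_time, rng_fu, rng_miss = _substreams(config.seed, 5)

    cov = _draw_covariates(config.covariate_specs, n, rng_cov)
    if n == 0:
        empty_traj = trajectories_to_frame([])
        cov.insert(0, "participant_id", pd.Series([], dtype=str))
        return cov, empty_traj, pd.Series([], dtype=str, name="pattern")

    logits = _membership_logits(config, cov)
    member = _draw_membership(logits, rng_mem)

    follow_up = np.maximum(
        rng_fu.normal(config.follow_up_mean, config.follow_up_sd, size=n), 1.0
    )

    ids = [f"{config.cohort_dialect}-{config.sex}-{i:06d}" for i in range(n)]
    trajs: list[Trajectory] = []
    label_values = []
    for i in range(n):
        spec = config.pattern_specs[member[i]]
        times, occurred = _draw_trajectory_times(spec, rng_time)
        trajs.append(
            Trajectory(
                participant_id=ids[i],
                times=tuple(times),
                occurred=tuple(bool(o) for o in occurred),
                follow_up=float(round(follow_up[i], 3)),
            )
        )
        label_values.append(spec.label.value)

    cov.insert(0, "participant_id", ids)
    cov.insert(1, "sex", config.sex)
    cov.insert(2, "follow_up_years", np.round(follow_up, 3))
    cov = inject_missingness(
        cov,
        config.missingness_rate,
        rng_miss,
        protect=("participant_id", "sex", "follow_up_years"),
    )
    labels = pd.Series(label_values, name="pattern")
    return cov, trajectories_to_frame(trajs), labels


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed,
    protect: Sequence[str] = ("participant_id",),
) -> pd.DataFrame:
    """Return a copy with each maskable cell set missing with probability ``rate``.

    Missingness is MCAR: every cell outside the ``protect`` columns is
    masked independently.  ``seed`` may be an integer or a Generator.
    """
    if not (0 <= rate <= 1):
        raise ConfigError("rate must lie in [0, 1]")
    out = table.copy()
    if rate == 0 or out.empty:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for col in out.columns:
        if col in protect:
            continue
        mask = rng.random(len(out)) < rate
        if isinstance(out[col].dtype, pd.CategoricalDtype):
            out.loc[mask, col] = np.nan
        else:
            out[col] = out[col].astype(object) if out[col].dtype == bool else out[col]
            out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# Reference stratum configurations
# ---------------------------------------------------------------------------

# Cluster sizes per stratum (counts partition the stratum exactly):
# (EarlyHyp, LateHyp, FirstDM, FirstHD, Healthy)
_CLUSTER_COUNTS = {
    ("uk", "male"): (370, 450, 126, 199, 7313),
    ("uk", "female"): (241, 339, 101, 71, 8490),
    ("elsa", "male"): (415, 305, 81, 88, 1981),
    ("elsa", "female"): (689, 499, 167, 100, 2837),
}

# First-disease onset windows as fractions of follow-up.  EarlyHyp and
# LateHyp windows are shared across strata; FirstDM/FirstHD windows vary
# by stratum; the Healthy window governs its rare, late, isolated events.
_WINDOWS = {
    ("uk", "male"): {"FirstDM": (0.02, 0.7), "FirstHD": (0.02, 0.7), "Healthy": (0.5, 1.0)},
    ("uk", "female"): {"FirstDM": (0.02, 0.7), "FirstHD": (0.02, 0.6), "Healthy": (0.5, 1.0)},
    ("elsa", "male"): {"FirstDM": (0.1, 0.7), "FirstHD": (0.02, 0.6), "Healthy": (0.76, 1.0)},
    ("elsa", "female"): {"FirstDM": (0.02, 0.6), "FirstHD": (0.02, 0.6), "Healthy": (0.76, 1.0)},
}

# Per-pattern disease incidences (HYP, DM, HD, STK).  The designated
# first disease has incidence 1; secondary incidences are set so the
# most frequent ordered trajectories match the reference frequencies.
_INCIDENCES = {
    ("uk", "male"): {
        "EarlyHyp": (1.0, 0.025, 0.035, 0.005),
        "LateHyp": (1.0, 0.04, 0.055, 0.01),
        "FirstDM": (0.55, 1.0, 0.08, 0.01),
        "FirstHD": (0.48, 0.05, 1.0, 0.01),
        "Healthy": (0.002, 0.004, 0.006, 0.001),
    },
    ("uk", "female"): {
        "EarlyHyp": (1.0, 0.025, 0.015, 0.003),
        "LateHyp": (1.0, 0.03, 0.033, 0.005),
        "FirstDM": (0.50, 1.0, 0.02, 0.005),
        "FirstHD": (0.42, 0.02, 1.0, 0.005),
        "Healthy": (0.001, 0.003, 0.002, 0.0005),
    },
    ("elsa", "male"): {
        "EarlyHyp": (1.0, 0.08, 0.05, 0.01),
        "LateHyp": (1.0, 0.075, 0.03, 0.005),
        "FirstDM": (0.55, 1.0, 0.04, 0.01),
        "FirstHD": (0.52, 0.12, 1.0, 0.015),
        "Healthy": (0.058, 0.02, 0.026, 0.005),
    },
    ("elsa", "female"): {
        "EarlyHyp": (1.0, 0.078, 0.04, 0.008),
        "LateHyp": (1.0, 0.07, 0.028, 0.004),
        "FirstDM": (0.46, 1.0, 0.04, 0.01),
        "FirstHD": (0.60, 0.08, 1.0, 0.01),
        "Healthy": (0.056, 0.025, 0.014, 0.004),
    },
}

_FIRST_DISEASE = {
    "EarlyHyp": DiseaseCode.HYP,
    "LateHyp": DiseaseCode.HYP,
    "FirstDM": DiseaseCode.DM,
    "FirstHD": DiseaseCode.HD,
    "Healthy": None,
}

_FOLLOW_UP = {"uk": (10.9, 0.6), "elsa": (12.3, 0.7)}

# Continuous clinical covariates shared by both dialects.  Means/SDs are
# plausible mid-life population values used as documented conventions.
_CLINICAL = [
    ("bmi", 27.0, 4.5),
    ("waist_hip", 0.87, 0.09),
    ("sbp", 129.0, 16.0),
    ("dbp", 79.0, 10.0),
    ("heart_rate", 69.0, 11.0),
    ("cholesterol", 5.7, 1.1),
    ("glucose", 5.1, 1.0),
    ("ldl", 3.5, 0.85),
    ("hdl", 1.45, 0.38),
    ("hba1c", 5.4, 0.55),
    ("triglycerides", 1.6, 0.9),
]

# Default membership effects: modest, epidemiologically signed shifts so
# that pattern membership is genuinely covariate-dependent.  Continuous
# effects are log-odds per SD; categorical effects are per-level shifts.
_CLINICAL_EFFECTS = {
    "bmi": {"FirstDM": 0.35, "EarlyHyp": 0.2},
    "waist_hip": {"FirstDM": 0.25, "FirstHD": 0.15},
    "sbp": {"EarlyHyp": 0.45, "LateHyp": 0.3},
    "dbp": {"EarlyHyp": 0.3, "LateHyp": 0.2},
    "glucose": {"FirstDM": 0.5},
    "hba1c": {"FirstDM": 0.35},
    "hdl": {"FirstHD": -0.2, "Healthy": 0.1},
    "triglycerides": {"FirstDM": 0.2, "FirstHD": 0.15},
}


def _clinical_specs() -> list[CovariateSpec]:
    out = []
    for name, mean, sd in _CLINICAL:
        out.append(
            CovariateSpec(
                name=name,
                kind="continuous",
                mean=mean,
                sd=sd,
                effects=_CLINICAL_EFFECTS.get(name, {}),
            )
        )
    return out


def _uk_covariates() -> list[CovariateSpec]:
    cat = CovariateSpec
    return [
        cat("age", "continuous", mean=55.1, sd=7.6,
            effects={"LateHyp": 0.3, "FirstHD": 0.25, "Healthy": -0.1}),
        cat("education", "categorical",
            levels=("none", "secondary", "university"), probs=(0.2, 0.45, 0.35),
            effects={"Healthy": {"university": 0.4},
                     "FirstDM": {"secondary": 0.3},
                     "LateHyp": {"secondary": 0.2}}),
        cat("smoking", "categorical",
            levels=("never", "past", "current"), probs=(0.55, 0.34, 0.11),
            effects={"FirstHD": {"current": 0.5, "past": 0.25},
                     "EarlyHyp": {"current": 0.4},
                     "Healthy": {"never": 0.3}}),
        cat("past_smoking", "categorical",
            levels=("never", "tried", "occasionally", "most_days"),
            probs=(0.5, 0.2, 0.12, 0.18),
            effects={"FirstHD": {"most_days": 0.45}}),
        cat("alcohol", "categorical",
            levels=("never", "past", "current"), probs=(0.08, 0.04, 0.88),
            effects={"LateHyp": {"current": 0.2}}),
        cat("ethnicity", "categorical",
            levels=("white", "not_white"), probs=(0.91, 0.09),
            effects={"Healthy": {"white": 0.15}}),
        cat("physical_activity", "continuous", mean=60.0, sd=40.0,
            effects={"Healthy": 0.15, "FirstHD": -0.15}),
        cat("sleep_problem", "categorical",
            levels=("never_rarely", "sometimes", "usually"), probs=(0.25, 0.47, 0.28),
            effects={"EarlyHyp": {"usually": 0.3}, "LateHyp": {"never_rarely": -0.2}}),
        cat("townsend", "continuous", mean=-1.3, sd=3.0,
            effects={"Healthy": -0.15, "FirstDM": 0.2}),
        cat("fruit_veg_intake", "continuous", mean=5.0, sd=2.5),
        cat("live_with_others", "categorical", levels=("yes", "no"), probs=(0.8, 0.2)),
        cat("coffee", "categorical", levels=("yes", "no"), probs=(0.78, 0.22)),
        cat("coffee_type", "categorical",
            levels=("decaffeinated", "instant", "ground", "other"),
            probs=(0.2, 0.45, 0.3, 0.05)),
    ] + _clinical_specs()


def _elsa_covariates() -> list[CovariateSpec]:
    cat = CovariateSpec
    return [
        cat("age", "continuous", mean=50.8, sd=7.4,
            effects={"LateHyp": 0.3, "FirstHD": 0.25, "Healthy": -0.1}),
        cat("education", "categorical",
            levels=("elementary", "secondary", "university"), probs=(0.18, 0.37, 0.45),
            effects={"Healthy": {"university": 0.45},
                     "LateHyp": {"secondary": 0.25},
                     "FirstHD": {"university": -0.3}}),
        cat("smoking", "categorical",
            levels=("never", "past", "current"), probs=(0.57, 0.3, 0.13),
            effects={"FirstHD": {"current": 0.5, "never": -0.25},
                     "Healthy": {"never": 0.3}}),
        cat("alcohol", "categorical",
            levels=("none", "moderate", "excessive"), probs=(0.32, 0.58, 0.1),
            effects={"EarlyHyp": {"none": 0.25}, "FirstHD": {"none": 0.2}}),
        cat("ethnicity", "categorical",
            levels=("white", "not_white"), probs=(0.57, 0.43),
            effects={"Healthy": {"white": 0.25}, "EarlyHyp": {"not_white": 0.3}}),
        cat("physical_activity", "categorical",
            levels=("weak", "moderate", "strong"), probs=(0.6, 0.25, 0.15),
            effects={"FirstHD": {"weak": 0.25, "moderate": -0.2}}),
        cat("marital_status", "categorical", levels=("single", "not_single"),
            probs=(0.35, 0.65)),
        cat("sleep_problem", "categorical", levels=("yes", "no"), probs=(0.45, 0.55),
            effects={"EarlyHyp": {"yes": 0.2}}),
        cat("income", "continuous", mean=1400.0, sd=900.0,
            effects={"Healthy": 0.2}),
        cat("fruit_intake", "categorical",
            levels=("high", "daily", "weekly", "rarely"), probs=(0.3, 0.35, 0.22, 0.13)),
        cat("coffee", "categorical",
            levels=("no", "yes_caffeinated", "yes_decaffeinated"),
            probs=(0.12, 0.82, 0.06),
            effects={"EarlyHyp": {"yes_caffeinated": 0.2}}),
        cat("mother_edu", "categorical",
            levels=("never_attended", "incomplete_elementary", "elementary",
                    "secondary", "undergraduate"),
            probs=(0.12, 0.35, 0.25, 0.18, 0.10)),
        cat("hyp_family", "categorical", levels=("yes", "no"), probs=(0.55, 0.45),
            effects={"EarlyHyp": {"yes": 0.25}}),
        cat("diab_family", "categorical", levels=("yes", "no"), probs=(0.35, 0.65),
            effects={"FirstDM": {"yes": 0.6}}),
        cat("heartdis_family", "categorical", levels=("yes", "no"), probs=(0.4, 0.6),
            effects={"FirstHD": {"yes": 0.3}}),
        cat("stroke_family", "categorical", levels=("yes", "no"), probs=(0.2, 0.8)),
        cat("suddeath_family", "categorical", levels=("yes", "no"), probs=(0.15, 0.85)),
    ] + _clinical_specs()


def stratum_config(
    cohort_dialect: str,
    sex: str,
    n: Optional[int] = None,
    seed: int = 0,
    missingness_rate: float = 0.03,
) -> SyntheticConfig:
    """Frozen generator configuration emulating one reference stratum.

    Mixing proportions equal the stratum's reported cluster-size
    fractions; first-onset windows follow the pattern definitions
    (EarlyHyp within 40% of follow-up, LateHyp within 40–80%, FirstDM and
    FirstHD within stratum-specific windows; Healthy events rare, late
    and isolated).  ``n`` defaults to the stratum's reference size.
    """
    key = (cohort_dialect, sex)
    if key not in _CLUSTER_COUNTS:
        raise ConfigError(
            f"unknown stratum {key!r}; expected dialect in ('uk', 'elsa') "
            "and sex in ('male', 'female')"
        )
    counts = _CLUSTER_COUNTS[key]
    total = sum(counts)
    order = ("EarlyHyp", "LateHyp", "FirstDM", "FirstHD", "Healthy")
    # Interior to the descriptive intervals ((0, 0.4] and (0.4, 0.8]) so the
    # planted patterns are separated by a density gap and k-means-recoverable,
    # while keeping the reported mean onset times (~0.22 and ~0.62).
    windows = {
        "EarlyHyp": (0.05, 0.38),
        "LateHyp": (0.44, 0.8),
        **_WINDOWS[key],
    }
    specs = []
    props = [c / total for c in counts]
    props[-1] = 1.0 - sum(props[:-1])  # exact partition
    for lab, prop in zip(order, props):
        specs.append(
            PatternSpec(
                label=PatternLabel(lab),
                mixing_proportion=prop,
                incidence=_INCIDENCES[key][lab],
                first_disease=_FIRST_DISEASE[lab],
                first_time_window=windows[lab],
            )
        )
    fu_mean, fu_sd = _FOLLOW_UP[cohort_dialect]
    covs = _uk_covariates() if cohort_dialect == "uk" else _elsa_covariates()
    return SyntheticConfig(
        n=total if n is None else n,
        cohort_dialect=cohort_dialect,
        sex=sex,
        seed=seed,
        pattern_specs=tuple(specs),
        covariate_specs=tuple(covs),
        missingness_rate=missingness_rate,
        follow_up_mean=fu_mean,
        follow_up_sd=fu_sd,
    )


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, PatternLabel):
        return obj.value
    if isinstance(obj, DiseaseCode):
        return obj.name
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def _pattern_from_dict(d: dict) -> PatternSpec:
    fd = d.get("first_disease")
    return PatternSpec(
        label=PatternLabel(d["label"]),
        mixing_proportion=float(d["mixing_proportion"]),
        incidence=tuple(float(x) for x in d["incidence"]),
        first_disease=None if fd is None else DiseaseCode[fd],
        first_time_window=tuple(float(x) for x in d["first_time_window"]),
        secondary_delay_frac=tuple(
            float(x) for x in d.get("secondary_delay_frac", (0.6, 1.0))
        ),
    )


def _covariate_from_dict(d: dict) -> CovariateSpec:
    return CovariateSpec(
        name=d["name"],
        kind=d["kind"],
        levels=tuple(d["levels"]) if d.get("levels") else None,
        probs=tuple(float(x) for x in d["probs"]) if d.get("probs") else None,
        mean=float(d.get("mean", 0.0)),
        sd=float(d.get("sd", 1.0)),
        effects=d.get("effects", {}) or {},
    )


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cfg = SyntheticConfig(
        n=int(d["n"]),
        cohort_dialect=d["cohort_dialect"],
        sex=d["sex"],
        seed=int(d["seed"]),
        pattern_specs=tuple(_pattern_from_dict(p) for p in d["pattern_specs"]),
        covariate_specs=tuple(_covariate_from_dict(c) for c in d["covariate_specs"]),
        missingness_rate=float(d.get("missingness_rate", 0.0)),
        follow_up_mean=float(d.get("follow_up_mean", 11.0)),
        follow_up_sd=float(d.get("follow_up_sd", 0.6)),
    )
    cfg.validate()
    return cfg
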