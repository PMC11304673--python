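"""Incidence/timing summaries and group-comparison tests.

Summaries mirror the standard cohort-description tables: per-group and
per-disease event counts, incidence percentages and mean (sd) fractional
onset times among those who developed the disease, plus a partition of
participants by number of diseases developed during follow-up.  Group
comparisons use Pearson's chi-square (uncorrected), one-way ANOVA and
Kruskal-Wallis (tie-corrected), all at a 0.05 significance level.  No
multiple-testing adjustment is applied; raw p-values are reported.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trajectory import DiseaseCode, Trajectory, N_DISEASES

__all__ = [
    "IncidenceSummary",
    "incidence_table",
    "disease_count_summary",
    "compare_groups",
    "round_half_up",
    "ALPHA",
]

ALPHA = 0.05


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero to the printed precision (1 decimal default).

    Used for display values so that e.g. 100 * 1018/8458 = 12.035 prints
    as 12.0 and 0.25 at 1 decimal prints as 0.3, matching conventional
    table rounding rather than banker's rounding.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class IncidenceSummary:
    """Per-group disease incidence and occurrence timing."""

    group: str
    n: int
    count: dict[str, int]  # per disease
    incidence_pct: dict[str, float]  # 100 * count / n, unrounded
    mean_time: dict[str, Optional[float]]  # among occurred; None if no events
    sd_time: dict[str, Optional[float]]

    def display_incidence(self, disease: str, ndigits: int = 1) -> float:
        return round_half_up(self.incidence_pct[disease], ndigits)


def incidence_table(
    trajectories: Sequence[Trajectory],
    group_labels: Sequence[str],
) -> list[IncidenceSummary]:
    """Per-group, per-disease incidence and mean (sd) fractional onset time.

    Every trajectory must carry a group label.  An empty group yields
    zero counts with timing reported as None.
    """
    if len(trajectories) != len(group_labels):
        raise ValueError("every trajectory needs a group label")
    groups = pd.unique(pd.Series(group_labels))
    out = []
    for g in groups:
        members = [t for t, lab in zip(trajectories, group_labels) if lab == g]
        n = len(members)
        count, inc, mean_t, sd_t = {}, {}, {}, {}
        for d in DiseaseCode:
            times = [t.times[d] for t in members if t.occurred[d]]
            count[d.label] = len(times)
            inc[d.label] = 100.0 * len(times) / n if n else 0.0
            mean_t[d.label] = float(np.mean(times)) if times else None
            sd_t[d.label] = (
                float(np.std(times, ddof=1)) if len(times) > 1 else (0.0 if times else None)
            )
        out.append(
            IncidenceSummary(
                group=str(g), n=n, count=count, incidence_pct=inc,
                mean_time=mean_t, sd_time=sd_t,
            )
        )
    return out


def disease_count_summary(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Partition participants by number of diseases developed (0..4).

    Returns a frame with columns ``n_diseases``, ``count``, ``pct``;
    percentages are of the full input and sum to 100 up to rounding.
    """
    n = len(trajectories)
    counts = np.zeros(N_DISEASES + 1, dtype=int)
    for t in trajectories:
        counts[t.n_diseases] += 1
    return pd.DataFrame(
        {
            "n_diseases": np.arange(N_DISEASES + 1),
            "count": counts,
            "pct": 100.0 * counts / n if n else np.zeros(N_DISEASES + 1),
        }
    )


def compare_groups(
    data: Sequence,
    grouping: Sequence,
    test: str,
) -> tuple[float, float, bool]:
    """Compare groups by the named test; returns (statistic, p, significant).

    ``test`` is one of ``"chi_square"`` (categorical data; Pearson,
    no continuity correction), ``"anova"`` (one-way) or
    ``"kruskal_wallis"`` (tie-corrected).  Significance is judged at
    p < 0.05.  Empty groups raise; a chi-square expected cell below 1
    triggers a warning rather than an error.
    """
    s = pd.Series(list(data))
    g = pd.Series(list(grouping))
    if len(s) != len(g):
        raise ValueError("data and grouping must have equal length")
    keep = s.notna() & g.notna()
    s, g = s[keep], g[keep]
    group_values = [s[g == lev] for lev in pd.unique(g)]
    if len(group_values) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) == 0 for v in group_values):
        raise ValueError("a group has zero observations")

    if test == "chi_square":
        table = pd.crosstab(g, s).to_numpy()
        if table.shape[1] < 2:
            # a single observed category: no association measurable
            return 0.0, 1.0, False
        stat, p, _, expected = sps.chi2_contingency(table, correction=False)
        if expected.min() < 1:
            warnings.warn(
                f"chi-square expected cell count {expected.min():.3g} < 1; "
                "the asymptotic p-value may be unreliable",
                stacklevel=2,
            )
        return float(stat), float(p), bool(p < ALPHA)
    if test == "anova":
        arrays = [np.asarray(v, dtype=float) for v in group_values]
        if np.ptp(np.concatenate(arrays)) == 0:
            return 0.0, 1.0, False
        stat, p = sps.f_oneway(*arrays)
        return float(stat), float(p), bool(p < ALPHA)
    if test == "kruskal_wallis":
        arrays = [np.asarray(v, dtype=float) for v in group_values]
        if np.ptp(np.concatenate(arrays)) == 0:
            return 0.0, 1.0, False
        stat, p = sps.kruskal(*arrays)
        return float(stat), float(p), bool(p < ALPHA)
    raise ValueError(f"unknown test {test!r}")
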