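"""Fractional-time encoding of cardiometabolic disease trajectories.

The cardiometabolic continuum (CMC) of one participant is the ordered
sequence of onsets of four diseases — hypertension (HYP), diabetes
mellitus (DM), heart disease (HD: angina, myocardial infarction or heart
failure) and stroke (STK) — over a fixed follow-up window.  A trajectory
is encoded as the 4-tuple ``(t_HYP, t_DM, t_HD, t_STK)`` where ``t_i`` is
the onset time of disease *i* divided by the follow-up duration, so that
``0 < t_i <= 1``, with ``t_i = 1`` when the disease never occurred.  This
bounded encoding preserves temporal ordering while keeping absent
diseases on the same scale as late-onset ones, which is what makes the
4-tuples directly clusterable.

Participants with any of the four diseases already present at baseline
are excluded upstream; an event at time 0 is therefore rejected here
rather than clamped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseCode",
    "EventRecord",
    "Trajectory",
    "encode_trajectory",
    "first_disease",
    "pattern_string",
    "NO_DISEASE_PATTERN",
    "read_events_csv",
    "write_events_csv",
    "trajectories_to_frame",
    "frame_to_trajectories",
]

#: Label used when no disease occurred during follow-up.
NO_DISEASE_PATTERN = "None Disease"

#: Separator used in ordered-pattern strings, read as "followed by".
ARROW = "→"


class DiseaseCode(enum.IntEnum):
    """The four cardiometabolic diseases, in canonical tuple order."""

    HYP = 0  # hypertension
    DM = 1   # diabetes mellitus
    HD = 2   # heart disease: angina, myocardial infarction, heart failure
    STK = 3  # stroke

    @property
    def label(self) -> str:
        return self.name


N_DISEASES = len(DiseaseCode)


@dataclass(frozen=True)
class EventRecord:
    """One incident disease diagnosis during follow-up.

    Times are in years from baseline.  Baseline-prevalent disease
    (``time_from_baseline == 0``) is an exclusion criterion and rejected.
    """

    disease: DiseaseCode
    time_from_baseline: float
    follow_up: float

    def __post_init__(self) -> None:
        if self.follow_up <= 0:
            raise ValueError(f"follow_up must be positive, got {self.follow_up}")
        if not (0 < self.time_from_baseline <= self.follow_up):
            raise ValueError(
                f"event time for {self.disease.label} must lie in "
                f"(0, {self.follow_up}], got {self.time_from_baseline}"
            )


@dataclass(frozen=True)
class Trajectory:
    """A participant's encoded CMC trajectory.

    ``times[i]`` is the fractional occurrence time of canonical disease
    ``i``; ``occurred[i]`` distinguishes an event exactly at the end of
    follow-up (``t_i == 1`` with ``occurred``) from no event at all.
    """

    participant_id: str
    times: tuple[float, float, float, float]
    occurred: tuple[bool, bool, bool, bool]
    follow_up: float

    def __post_init__(self) -> None:
        if len(self.times) != N_DISEASES or len(self.occurred) != N_DISEASES:
            raise ValueError("times and occurred must each have 4 entries")
        for d in DiseaseCode:
            t = self.times[d]
            if not (0 < t <= 1):
                raise ValueError(f"t_{d.label} = {t} outside (0, 1]")
            if not self.occurred[d] and t != 1.0:
                raise ValueError(f"{d.label}: non-occurrence requires t = 1, got {t}")

    @property
    def n_diseases(self) -> int:
        return int(sum(self.occurred))

    def event_times_years(self) -> dict[DiseaseCode, float]:
        """Decode occurred fractional times back to years from baseline."""
        return {
            d: self.times[d] * self.follow_up for d in DiseaseCode if self.occurred[d]
        }


def encode_trajectory(
    events: Iterable[EventRecord],
    follow_up: float,
    participant_id: str = "",
) -> Trajectory:
    """Encode incident events into the fractional-time 4-tuple.

    Each occurred disease contributes ``t_i = time / follow_up``; absent
    diseases encode as 1.  An event exactly at the end of follow-up gives
    ``t_i = 1`` but keeps ``occurred`` set.

    Raises
    ------
    ValueError
        If ``follow_up <= 0``, an event's follow-up disagrees, a disease
        appears twice, or an event time falls outside ``(0, follow_up]``.
    """
    if follow_up <= 0:
        raise ValueError(f"follow_up must be positive, got {follow_up}")
    times = [1.0] * N_DISEASES
    occurred = [False] * N_DISEASES
    for ev in events:
        if ev.follow_up != follow_up:
            raise ValueError(
                f"event follow_up {ev.follow_up} != trajectory follow_up {follow_up}"
            )
        if occurred[ev.disease]:
            raise ValueError(f"duplicate event for disease {ev.disease.label}")
        occurred[ev.disease] = True
        times[ev.disease] = ev.time_from_baseline / follow_up
    return Trajectory(
        participant_id=participant_id,
        times=tuple(times),
        occurred=tuple(occurred),
        follow_up=follow_up,
    )


def _occurred_order(traj: Trajectory) -> list[DiseaseCode]:
    """Occurred diseases sorted by onset; ties broken by canonical index."""
    occ = [d for d in DiseaseCode if traj.occurred[d]]
    return sorted(occ, key=lambda d: (traj.times[d], int(d)))


def first_disease(traj: Trajectory) -> tuple[Optional[DiseaseCode], bool]:
    """Return (first disease on the continuum, tie flag).

    The first disease is the occurred disease with minimal fractional
    time; ties are broken by canonical order (HYP < DM < HD < STK) and
    flagged so reports can mark the ordering as ambiguous.  Returns
    ``(None, False)`` for a disease-free trajectory.
    """
    order = _occurred_order(traj)
    if not order:
        return None, False
    first = order[0]
    tie = any(
        traj.times[d] == traj.times[first] for d in order[1:]
    )
    return first, tie


def pattern_string(traj: Trajectory) -> str:
    """Ordered-pattern label, e.g. ``"DM→HYP"`` for diabetes then hypertension.

    Occurred diseases are sorted ascending by fractional time (canonical
    tie-break) and joined with an arrow read as "followed by".  A
    disease-free trajectory yields ``"None Disease"``.
    """
    order = _occurred_order(traj)
    if not order:
        return NO_DISEASE_PATTERN
    return ARROW.join(d.label for d in order)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_EVENT_COLS = {d: f"{d.label.lower()}_years" for d in DiseaseCode}
_T_COLS = {d: f"t_{d.label.lower()}" for d in DiseaseCode}
_OCC_COLS = {d: f"occ_{d.label.lower()}" for d in DiseaseCode}


def read_events_csv(path) -> list[Trajectory]:
    """Read a participant-events table and encode each row.

    Expected columns: ``participant_id``, ``sex``, ``follow_up_years``,
    then one event-year column per disease (``hyp_years`` ... ``stk_years``)
    with an empty cell / NA for non-occurrence.
    """
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        fu = float(row["follow_up_years"])
        events = [
            EventRecord(d, float(row[col]), fu)
            for d, col in _EVENT_COLS.items()
            if pd.notna(row[col])
        ]
        out.append(encode_trajectory(events, fu, participant_id=str(row["participant_id"])))
    return out


def write_events_csv(path, trajectories: Sequence[Trajectory], sex=None) -> None:
    """Write trajectories back to the participant-events CSV dialect."""
    rows = []
    for i, traj in enumerate(trajectories):
        row: dict = {
            "participant_id": traj.participant_id,
            "sex": sex[i] if sex is not None else "",
            "follow_up_years": traj.follow_up,
        }
        years = traj.event_times_years()
        for d, col in _EVENT_COLS.items():
            row[col] = years.get(d, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Tabular form: participant_id, t_hyp..t_stk, occ_hyp..occ_stk, follow_up."""
    data: dict = {"participant_id": [t.participant_id for t in trajectories]}
    for d in DiseaseCode:
        data[_T_COLS[d]] = [t.times[d] for t in trajectories]
    for d in DiseaseCode:
        data[_OCC_COLS[d]] = [t.occurred[d] for t in trajectories]
    data["follow_up"] = [t.follow_up for t in trajectories]
    return pd.DataFrame(data)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for _, row in df.iterrows():
        out.append(
            Trajectory(
                participant_id=str(row["participant_id"]),
                times=tuple(float(row[_T_COLS[d]]) for d in DiseaseCode),
                occurred=tuple(bool(row[_OCC_COLS[d]]) for d in DiseaseCode),
                follow_up=float(row["follow_up"]),
            )
        )
    return out


def time_matrix(trajectories: Sequence[Trajectory] | pd.DataFrame) -> np.ndarray:
    """The (n, 4) array of fractional times used as the clustering features."""
    if isinstance(trajectories, pd.DataFrame):
        return trajectories[[_T_COLS[d] for d in DiseaseCode]].to_numpy(float)
    return np.array([t.times for t in trajectories], dtype=float)
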