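"""Canonical pattern labels shared by the simulator, clustering and classifier."""

from __future__ import annotations

import enum


class PatternLabel(str, enum.Enum):
    """Named cardiometabolic-continuum patterns.

    The five substantive labels describe which disease opens the
    continuum and when; ``Unlabeled`` marks a discovered cluster that
    matches none of the labeling rules.
    """

    EARLY_HYP = "EarlyHyp"
    LATE_HYP = "LateHyp"
    FIRST_DM = "FirstDM"
    FIRST_HD = "FirstHD"
    HEALTHY = "Healthy"
    UNLABELED = "Unlabeled"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five substantive labels in a fixed reporting order.
CORE_LABELS = (
    PatternLabel.EARLY_HYP,
    PatternLabel.LATE_HYP,
    PatternLabel.FIRST_DM,
    PatternLabel.FIRST_HD,
    PatternLabel.HEALTHY,
)
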