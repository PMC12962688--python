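"""Smoking-status classes and questionnaire categorization.

The classifier distinguishes three self-reported smoking statuses with a
fixed ordinal coding used throughout (correlation analyses code current
smokers as 1, former as 2 and never smokers as 3).
"""

from __future__ import annotations

from enum import IntEnum
from typing import Optional

__all__ = ["SmokingStatus", "categorize_smoking_status", "STATUS_ORDER"]


class SmokingStatus(IntEnum):
    """The three smoking-status classes with their global ordinal codes."""

    CURRENT = 1
    FORMER = 2
    NEVER = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "SmokingStatus":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown smoking status label: {label!r}") from None


#: Canonical class order (current, former, never) used for all matrices/reports.
STATUS_ORDER = (SmokingStatus.CURRENT, SmokingStatus.FORMER, SmokingStatus.NEVER)


def categorize_smoking_status(raw_answer: int) -> Optional[SmokingStatus]:
    """Map a questionnaire answer code (1-6) to a smoking status.

    The underlying question is "What is your current smoking status?" with
    six ordered answers: daily smoking (1), weekly but not daily (2), less
    often than weekly (3), attempting to quit (4), has quit (5), has never
    smoked (6).

    Answers 1, 2 and 4 are categorized as current smokers, 5 as former and
    6 as never smokers. Answer 3 (occasional smokers) is excluded from
    training because the methylation profile of occasional smokers is
    ambiguous; ``None`` is returned for it.

    Parameters
    ----------
    raw_answer : int
        Answer code in 1..6.

    Returns
    -------
    SmokingStatus or None
        ``None`` means the sample is excluded (occasional smoker).
    """
    answer = int(raw_answer)
    if answer < 1 or answer > 6:
        raise ValueError(f"questionnaire answer must be in 1..6, got {raw_answer}")
    if answer in (1, 2, 4):
        return SmokingStatus.CURRENT
    if answer == 5:
        return SmokingStatus.FORMER
    if answer == 6:
        return SmokingStatus.NEVER
    return None  # answer 3: occasional smoker, excluded
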