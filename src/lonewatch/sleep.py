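"""Nightly sleep features.

Sleep detection happens on the watch; this module consumes the nightly
summaries it produces and derives the two indicator features (sleep
quality: WASO <= 20 min; sufficient sleep: TST in the 7-8.5 h band, both
bounds inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

WASO_QUALITY_MAX_MIN = 20.0
TST_SUFFICIENT_MIN = 420.0  # 7 h
TST_SUFFICIENT_MAX = 510.0  # 8.5 h

SLEEP_FEATURES = (
    "tst",
    "fragmentation",
    "waso",
    "avg_hand_movement",
    "sleep_quality",
    "sufficient_sleep",
)


@dataclass
class SleepNight:
    """One night's summary, attributed to the date the sleep period ends."""

    participant_id: str
    date: pd.Timestamp
    tst: float  # minutes
    fragmentation: int
    waso: float  # minutes
    avg_hand_movement: float
    sleep_onset: pd.Timestamp
    sleep_offset: pd.Timestamp
    valid: bool = True

    def __post_init__(self) -> None:
        if self.sleep_offset <= self.sleep_onset:
            raise ValueError("sleep_offset must be after sleep_onset")

    @property
    def interval_min(self) -> float:
        return (self.sleep_offset - self.sleep_onset).total_seconds() / 60.0


def sleep_quality_indicator(waso: Optional[float]) -> Optional[bool]:
    """True iff wake-after-sleep-onset is at most 20 minutes."""
    if waso is None or (isinstance(waso, float) and math.isnan(waso)):
        return None
    return waso <= WASO_QUALITY_MAX_MIN


def sufficient_sleep(tst: Optional[float]) -> Optional[bool]:
    """True iff total sleep time lies in [420, 510] minutes (7-8.5 h)."""
    if tst is None or (isinstance(tst, float) and math.isnan(tst)):
        return None
    return TST_SUFFICIENT_MIN <= tst <= TST_SUFFICIENT_MAX


def derive_sleep_row(night: SleepNight) -> Optional[dict]:
    """Sleep feature sub-row for one day; ``None`` for an invalid night."""
    if not night.valid:
        return None
    return {
        "tst": night.tst,
        "fragmentation": float(night.fragmentation),
        "waso": night.waso,
        "avg_hand_movement": night.avg_hand_movement,
        "sleep_quality": float(sleep_quality_indicator(night.waso)),
        "sufficient_sleep": float(sufficient_sleep(night.tst)),
    }
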