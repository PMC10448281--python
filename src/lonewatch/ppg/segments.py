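"""Raw PPG segments and fixed-length analysis windows.

The watch records 12-minute pulse-waveform segments every other hour at a
low sampling rate (20 Hz). HRV analysis operates on non-overlapping
5-minute windows cut from each segment; a trailing remainder shorter than
the window length is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from lonewatch.errors import DegenerateSignalError

#: analysis window length (short-term HRV convention)
WINDOW_S = 300.0

RELIABLE = "reliable"
UNRELIABLE = "unreliable"
UNASSESSED = "unassessed"


@dataclass
class PPGSegment:
    """One continuous pulse-waveform recording."""

    participant_id: str
    start_time: pd.Timestamp
    fs_hz: float
    samples: np.ndarray
    #: optional ground-truth peak sample indices (synthetic data only)
    true_peaks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass
class PPGWindow:
    """A 5-minute slice of a segment, with a reliability verdict."""

    segment: PPGSegment
    start_offset: int  # sample index into the parent segment
    samples: np.ndarray
    reliability: str = UNASSESSED
    quality_features: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def fs_hz(self) -> float:
        return self.segment.fs_hz

    @property
    def start_time(self) -> pd.Timestamp:
        return self.segment.start_time + pd.Timedelta(
            seconds=self.start_offset / self.fs_hz
        )

    @property
    def true_peaks(self) -> Optional[np.ndarray]:
        """Ground-truth peaks falling inside this window, window-relative."""
        tp = self.segment.true_peaks
        if tp is None:
            return None
        lo, hi = self.start_offset, self.start_offset + len(self.samples)
        inside = tp[(tp >= lo) & (tp < hi)]
        return inside - lo


def window_segment(segment: PPGSegment, window_s: float = WINDOW_S) -> list[PPGWindow]:
    """Cut a segment into non-overlapping windows of ``window_s`` seconds.

    The trailing remainder shorter than one window is dropped, so a
    nominal 12-minute segment yields two 5-minute windows.
    """
    if len(segment.samples) == 0:
        raise DegenerateSignalError("empty segment")
    wlen = int(round(window_s * segment.fs_hz))
    n_windows = len(segment.samples) // wlen
    return [
        PPGWindow(
            segment=segment,
            start_offset=i * wlen,
            samples=segment.samples[i * wlen : (i + 1) * wlen],
        )
        for i in range(n_windows)
    ]
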