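"""Interbeat-interval error rejection.

Intervals implied by the detected peaks are screened twice: an absolute
physiological band, then a relative band around the window's own mean
interval (the mean is re-estimated iteratively as outliers are dropped,
so a single spurious beat cannot drag the band). A window that retains
too few intervals is marked unusable and propagates as missing HRV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ABS_BAND_MS = (300.0, 2000.0)
REL_BAND = 0.30
MIN_RETAINED = 10


@dataclass
class IBISeries:
    """Cleaned interbeat intervals (ms) for one analysis window."""

    intervals: np.ndarray
    peak_times: np.ndarray  # sample indices of the retained peaks (beat ends)
    rejected: list[tuple[int, str]] = field(default_factory=list)
    fs_hz: float = 20.0
    usable: bool = True

    @property
    def n_retained(self) -> int:
        return len(self.intervals)

    @property
    def covered_duration_min(self) -> float:
        return float(np.sum(self.intervals)) / 60000.0


def clean_ibis(
    peak_times: np.ndarray,
    fs_hz: float,
    abs_band_ms: tuple[float, float] = ABS_BAND_MS,
    rel_band: float = REL_BAND,
    min_retained: int = MIN_RETAINED,
) -> IBISeries:
    """Turn peak indices into a cleaned IBI series.

    Parameters
    ----------
    peak_times
        Detected peak sample indices (monotone increasing).
    fs_hz
        Sampling frequency used to convert indices to milliseconds.

    Notes
    -----
    Retained intervals satisfy both the absolute band and
    ``mean * (1 ± rel_band)`` where the mean is computed iteratively on
    the surviving intervals. Fewer than ``min_retained`` survivors mark
    the series unusable.
    """
    peak_times = np.asarray(peak_times)
    if len(peak_times) < 2:
        return IBISeries(
            intervals=np.empty(0),
            peak_times=np.empty(0, dtype=int),
            rejected=[],
            fs_hz=fs_hz,
            usable=False,
        )
    raw = np.diff(peak_times) / fs_hz * 1000.0
    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(raw), dtype=bool)

    lo, hi = abs_band_ms
    for i, ibi in enumerate(raw):
        if not lo <= ibi <= hi:
            keep[i] = False
            rejected.append((i, "absolute_band"))

    # relative band, mean re-estimated until stable
    while keep.any():
        mean = float(np.mean(raw[keep]))
        bad = keep & ((raw < (1 - rel_band) * mean) | (raw > (1 + rel_band) * mean))
        if not bad.any():
            break
        for i in np.flatnonzero(bad):
            rejected.append((int(i), "relative_band"))
        keep &= ~bad

    intervals = raw[keep]
    # peak_times[i + 1] ends interval i
    retained_peaks = peak_times[1:][keep]
    rejected.sort()
    return IBISeries(
        intervals=intervals,
        peak_times=retained_peaks,
        rejected=rejected,
        fs_hz=fs_hz,
        usable=len(intervals) >= min_retained,
    )


def clean_intervals(
    intervals: np.ndarray,
    fs_hz: float = 20.0,
    **kwargs,
) -> IBISeries:
    """Clean a pre-extracted interval list (ms) by the same rules.

    Convenience for the fast simulation path where intervals exist
    without a waveform; synthesises peak times from the cumulative sum.
    """
    intervals = np.asarray(intervals, dtype=float)
    peaks = np.concatenate(([0.0], np.cumsum(intervals))) / 1000.0 * fs_hz
    return clean_ibis(peaks, fs_hz, **kwargs)
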