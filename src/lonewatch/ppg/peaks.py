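"""Moving-average peak detection with an adaptive threshold.

Candidate thresholds raise the moving average by a percentage of the
signal's amplitude range; each candidate segments the signal into
above-threshold regions whose maxima are the candidate beats. The
threshold whose beats give the most regular interbeat intervals (lowest
IBI standard deviation) while implying a physiological heart rate is
selected.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

MA_WINDOW_S = 0.75
THRESHOLD_OFFSETS_PCT = (0, 5, 10, 15, 20, 25, 30)
HR_BOUNDS_BPM = (40.0, 180.0)


def _peaks_above(samples: np.ndarray, threshold: np.ndarray) -> np.ndarray:
    """Argmax of each contiguous above-threshold region."""
    above = samples > threshold
    if not above.any():
        return np.empty(0, dtype=int)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(samples)]))
    return np.array(
        [s + int(np.argmax(samples[s:e])) for s, e in zip(starts, ends)], dtype=int
    )


def detect_peaks(
    samples: np.ndarray,
    fs_hz: float,
    ma_window_s: float = MA_WINDOW_S,
    offsets_pct: tuple[int, ...] = THRESHOLD_OFFSETS_PCT,
    hr_bounds_bpm: tuple[float, float] = HR_BOUNDS_BPM,
) -> np.ndarray:
    """Detect pulse peaks in a filtered window; returns sample indices.

    Returns an empty array when no threshold yields at least two beats at
    a plausible heart rate (flat or hopeless signal).
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) == 0:
        return np.empty(0, dtype=int)
    amp_range = float(samples.max() - samples.min())
    if amp_range == 0.0:
        return np.empty(0, dtype=int)
    ma = uniform_filter1d(samples, size=max(int(round(ma_window_s * fs_hz)), 1))
    duration_min = len(samples) / fs_hz / 60.0

    best_peaks: np.ndarray | None = None
    best_sd = np.inf
    for off in offsets_pct:
        peaks = _peaks_above(samples, ma + off / 100.0 * amp_range)
        if len(peaks) < 2:
            continue
        hr = len(peaks) / duration_min
        if not hr_bounds_bpm[0] <= hr <= hr_bounds_bpm[1]:
            continue
        sd = float(np.std(np.diff(peaks)))
        if sd < best_sd:
            best_sd, best_peaks = sd, peaks
    if best_peaks is None:
        return np.empty(0, dtype=int)
    return best_peaks
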