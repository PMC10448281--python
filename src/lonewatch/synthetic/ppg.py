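"""Synthetic pulse waveforms with stored ground-truth peak times.

Each cardiac cycle is a fixed template — a systolic Gaussian bump plus a
smaller dicrotic bump — stretched to that cycle's interbeat interval and
sampled at the requested rate. The ground-truth peak of every cycle is
the argmax of the clean (noise-free) sampled waveform, so peak-detection
recovery can be asserted to within one sample period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lonewatch.errors import DegenerateSignalError, UndersamplingError
from lonewatch.ppg.segments import PPGSegment

# template phases/widths in cycle fractions; amplitudes in arbitrary units
SYSTOLIC_PHASE = 0.30
SYSTOLIC_SIGMA = 0.10
DICROTIC_PHASE = 0.65
DICROTIC_SIGMA = 0.10
DICROTIC_AMPLITUDE = 0.20

_MIN_FS_HZ = 7.0  # 2 x 3.5 Hz cardiac upper band


def _template(phase: np.ndarray, dicrotic_amplitude: float) -> np.ndarray:
    out = np.exp(-0.5 * ((phase - SYSTOLIC_PHASE) / SYSTOLIC_SIGMA) ** 2)
    if dicrotic_amplitude:
        out = out + dicrotic_amplitude * np.exp(
            -0.5 * ((phase - DICROTIC_PHASE) / DICROTIC_SIGMA) ** 2
        )
    return out


def generate_ppg(
    ibi_series: np.ndarray,
    fs_hz: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    participant_id: str = "synthetic",
    start_time: pd.Timestamp | None = None,
    dicrotic_amplitude: float = DICROTIC_AMPLITUDE,
) -> PPGSegment:
    """Render an IBI series (ms) into a sampled pulse waveform.

    Returns a :class:`~lonewatch.ppg.segments.PPGSegment` whose
    ``true_peaks`` holds one ground-truth peak index per cycle (argmax of
    the clean waveform within the cycle).
    """
    ibi_series = np.asarray(ibi_series, dtype=float)
    if len(ibi_series) == 0:
        raise DegenerateSignalError("empty ibi_series")
    if fs_hz < _MIN_FS_HZ:
        raise UndersamplingError(f"fs_hz {fs_hz} < {_MIN_FS_HZ} Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if start_time is None:
        start_time = pd.Timestamp("2021-01-01")

    cycle_starts_s = np.concatenate(([0.0], np.cumsum(ibi_series))) / 1000.0
    duration_s = cycle_starts_s[-1]
    n_samples = int(round(duration_s * fs_hz))
    t = np.arange(n_samples) / fs_hz

    # map each sample to its cycle and phase within the cycle
    cycle_idx = np.clip(
        np.searchsorted(cycle_starts_s, t, side="right") - 1, 0, len(ibi_series) - 1
    )
    phase = (t - cycle_starts_s[cycle_idx]) / (ibi_series[cycle_idx] / 1000.0)
    clean = _template(np.clip(phase, 0.0, 1.0), dicrotic_amplitude)

    true_peaks = []
    for i in range(len(ibi_series)):
        in_cycle = np.flatnonzero(cycle_idx == i)
        if len(in_cycle):
            true_peaks.append(in_cycle[np.argmax(clean[in_cycle])])
    samples = clean if noise_sd == 0 else clean + rng.normal(0.0, noise_sd, n_samples)

    return PPGSegment(
        participant_id=participant_id,
        start_time=start_time,
        fs_hz=fs_hz,
        samples=samples,
        true_peaks=np.asarray(true_peaks, dtype=int),
    )
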