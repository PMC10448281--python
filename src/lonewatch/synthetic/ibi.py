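"""Ground-truth interbeat-interval series with controllable variability.

The series is the raw material for both the waveform synthesiser and the
HRV parameter-recovery tests: its mean sets the heart rate, its standard
deviation the SDNN target, and an optional sinusoidal modulation plants
spectral power at a chosen frequency (so LF/HF behaviour is testable).
"""

from __future__ import annotations

import numpy as np

from lonewatch.errors import ParameterError

# fraction of the interval variance carried by the sinusoid (rest is white)
_MODULATION_VAR_FRACTION = 0.8


def generate_ibi_series(
    mean_hr_bpm: float,
    sdnn_target_ms: float,
    modulation_hz: float = 0.1,
    duration_s: float = 300.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate an interbeat-interval series (ms) covering ``duration_s``.

    Parameters
    ----------
    mean_hr_bpm
        Target mean heart rate, in [30, 220] beats/min.
    sdnn_target_ms
        Target standard deviation of the intervals. ``0`` yields a
        perfectly regular series.
    modulation_hz
        Frequency of the sinusoidal interval modulation. Most of the
        interval variance (80%) is placed at this frequency, the rest is
        white. ``0`` disables the sinusoid (all-white variability).
    duration_s
        Total covered duration; intervals are emitted until their sum
        reaches ``duration_s * 1000`` ms.
    seed
        Integer seed or a ``numpy.random.Generator``.

    Returns
    -------
    numpy.ndarray
        Interval series in milliseconds, ``sum ~= duration_s * 1000``.
    """
    if not 30.0 <= mean_hr_bpm <= 220.0:
        raise ParameterError(f"mean_hr_bpm {mean_hr_bpm} outside [30, 220]")
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    mean_ibi = 60000.0 / mean_hr_bpm
    if sdnn_target_ms < 0:
        raise ParameterError("sdnn_target_ms must be nonnegative")
    if sdnn_target_ms >= mean_ibi:
        raise ParameterError(
            f"sdnn_target_ms {sdnn_target_ms} >= mean interval {mean_ibi:.1f} ms"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(np.ceil(duration_s * 1000.0 / mean_ibi)) + 8
    if sdnn_target_ms == 0.0:
        intervals = np.full(n, mean_ibi)
    else:
        if modulation_hz > 0:
            sin_sd = sdnn_target_ms * np.sqrt(_MODULATION_VAR_FRACTION)
            white_sd = sdnn_target_ms * np.sqrt(1.0 - _MODULATION_VAR_FRACTION)
        else:
            sin_sd, white_sd = 0.0, sdnn_target_ms
        # beat times on the mean grid are accurate enough to place the modulation
        t = np.arange(n) * mean_ibi / 1000.0
        phase = rng.uniform(0, 2 * np.pi)
        intervals = (
            mean_ibi
            + sin_sd * np.sqrt(2.0) * np.sin(2 * np.pi * modulation_hz * t + phase)
            + rng.normal(0.0, white_sd, n)
        )
        intervals = np.clip(intervals, 0.35 * mean_ibi, 1.9 * mean_ibi)

    cum = np.cumsum(intervals)
    keep = int(np.searchsorted(cum, duration_s * 1000.0)) + 1
    return intervals[: min(keep, n)]
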