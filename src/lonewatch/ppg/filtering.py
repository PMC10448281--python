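"""Zero-phase bandpass for the cardiac frequency band."""

from __future__ import annotations

import numpy as np
from scipy import signal

from lonewatch.errors import ParameterError

LOW_HZ = 0.7
HIGH_HZ = 3.5


def bandpass(
    samples: np.ndarray,
    fs_hz: float,
    low_hz: float = LOW_HZ,
    high_hz: float = HIGH_HZ,
    order: int = 2,
) -> np.ndarray:
    """Bidirectional Butterworth bandpass (zero phase, peaks keep their time).

    Raises
    ------
    ParameterError
        If ``high_hz`` is at or above the Nyquist frequency.
    """
    if high_hz >= fs_hz / 2:
        raise ParameterError(
            f"high cutoff {high_hz} Hz >= Nyquist {fs_hz / 2} Hz"
        )
    if low_hz <= 0 or low_hz >= high_hz:
        raise ParameterError("need 0 < low_hz < high_hz")
    samples = np.asarray(samples, dtype=float)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, samples)
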