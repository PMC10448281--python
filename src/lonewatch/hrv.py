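"""Heart rate and HRV parameters from cleaned interbeat intervals.

Time domain: AVNN (mean of normal IBIs), SDNN (population SD), RMSSD
(root mean square of successive differences). Frequency domain: power in
the LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands and their ratio, from a
least-squares (Lomb-Scargle) spectrum of the unevenly time-stamped
interval sequence — no resampling, which would bias spectra derived from
a 20 Hz waveform. A cubic-interpolation + Welch estimator is available
via ``method="welch"``.

The nightly resting record is the reliable sleep-period window with the
lowest heart rate; its HRV parameters are the day's HRV features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate, signal

from lonewatch.ppg.cleaning import IBISeries

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
MIN_INTERVALS_FREQ = 10
MIN_SPAN_S_FREQ = 120.0  # LF needs >= 1/0.04 s of signal

HRV_FEATURES = ("hr", "avnn", "sdnn", "rmssd", "lf", "hf", "lf_hf")


@dataclass
class HRVRecord:
    """HR plus the six HRV parameters for one analysis window."""

    hr: float
    avnn: float
    sdnn: float
    rmssd: float
    lf: float
    hf: float
    lf_hf: float
    window_start: Optional[object] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in HRV_FEATURES}


def compute_hr(ibis: IBISeries) -> float:
    """Heart rate as retained beats per minute of covered duration."""
    if not ibis.usable or ibis.n_retained == 0:
        return np.nan
    return ibis.n_retained / ibis.covered_duration_min


def compute_time_domain(ibis: IBISeries) -> tuple[float, float, float]:
    """(AVNN, SDNN, RMSSD) in ms; NaNs when fewer than two intervals."""
    x = np.asarray(ibis.intervals, dtype=float)
    if len(x) < 2:
        return (np.nan, np.nan, np.nan)
    avnn = float(np.mean(x))
    sdnn = float(np.std(x))  # population SD
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return (avnn, sdnn, rmssd)


def _lombscargle(
    times_s: np.ndarray, values: np.ndarray, omegas: np.ndarray
) -> np.ndarray:
    """Classic unnormalized Lomb periodogram, vectorized over frequencies."""
    wt = omegas[:, None] * times_s[None, :]
    cw, sw = np.cos(wt), np.sin(wt)
    s2 = 2.0 * (sw * cw).sum(axis=1)
    c2 = (cw * cw - sw * sw).sum(axis=1)
    tau_w = 0.5 * np.arctan2(s2, c2)
    ct, st = np.cos(tau_w)[:, None], np.sin(tau_w)[:, None]
    cosa = cw * ct + sw * st
    sina = sw * ct - cw * st
    yc = cosa @ values
    ys = sina @ values
    cc = (cosa**2).sum(axis=1)
    ss = (sina**2).sum(axis=1)
    return 0.5 * (yc**2 / cc + ys**2 / ss)


def _lomb_psd(times_s: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    span = times_s[-1] - times_s[0]
    freqs = np.arange(0.03, 0.42, 0.002)
    pgram = _lombscargle(times_s, values - values.mean(), 2 * np.pi * freqs)
    # scale so a sinusoid of amplitude A integrates to ~A^2/2 over its peak
    psd = pgram * 2.0 * span / len(values)
    return freqs, psd


def _welch_psd(times_s: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fs = 4.0
    grid = np.arange(times_s[0], times_s[-1], 1.0 / fs)
    spline = interpolate.CubicSpline(times_s, values)
    resampled = spline(grid)
    nperseg = min(len(grid), 256)
    return signal.welch(resampled - resampled.mean(), fs=fs, nperseg=nperseg)


def compute_freq_domain(
    ibis: IBISeries, method: str = "lomb"
) -> tuple[float, float, float]:
    """(LF, HF, LF/HF); LF/HF is NaN when HF power is zero.

    Requires at least ``MIN_INTERVALS_FREQ`` retained intervals spanning
    ``MIN_SPAN_S_FREQ`` seconds; otherwise all three are NaN.
    """
    if method not in ("lomb", "welch"):
        raise ValueError(f"unknown spectral method {method!r}")
    x = np.asarray(ibis.intervals, dtype=float)
    if len(x) < MIN_INTERVALS_FREQ:
        return (np.nan, np.nan, np.nan)
    times_s = np.cumsum(x) / 1000.0
    if times_s[-1] - times_s[0] < MIN_SPAN_S_FREQ:
        return (np.nan, np.nan, np.nan)
    if np.ptp(x) == 0.0:
        return (0.0, 0.0, np.nan)
    if method == "lomb":
        freqs, psd = _lomb_psd(times_s, x)
    else:
        freqs, psd = _welch_psd(times_s, x)

    def band_power(band: tuple[float, float]) -> float:
        m = (freqs >= band[0]) & (freqs < band[1])
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    lf = band_power(LF_BAND)
    hf = band_power(HF_BAND)
    lf_hf = lf / hf if hf > 0 else np.nan
    return (lf, hf, lf_hf)


def compute_hrv_record(
    ibis: IBISeries, window_start=None, method: str = "lomb"
) -> Optional[HRVRecord]:
    """All seven parameters for one window; ``None`` if unusable."""
    if not ibis.usable:
        return None
    hr = compute_hr(ibis)
    avnn, sdnn, rmssd = compute_time_domain(ibis)
    lf, hf, lf_hf = compute_freq_domain(ibis, method=method)
    return HRVRecord(
        hr=hr, avnn=avnn, sdnn=sdnn, rmssd=rmssd, lf=lf, hf=hf, lf_hf=lf_hf,
        window_start=window_start,
    )


@dataclass
class RestingRecord:
    """The lowest-HR sleep-period window of one night."""

    participant_id: str
    date: object
    record: HRVRecord


def select_resting(
    night_windows: Sequence[HRVRecord],
    sleep_interval: tuple,
    participant_id: str = "",
    date=None,
) -> Optional[RestingRecord]:
    """Pick the minimum-HR window whose start lies in the sleep interval.

    Ties break toward the earliest window start. Returns ``None`` when
    no reliable window falls inside the interval.
    """
    onset, offset = sleep_interval
    candidates = [
        r
        for r in night_windows
        if r.window_start is not None
        and onset <= r.window_start <= offset
        and np.isfinite(r.hr)
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda r: (r.hr, r.window_start))
    return RestingRecord(participant_id=participant_id, date=date, record=best)
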