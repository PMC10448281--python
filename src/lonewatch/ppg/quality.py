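"""One-class reliability gate for PPG windows.

Motion artifacts corrupt wrist PPG; before any HRV is computed each
window is scored by a one-class support vector machine trained on
morphological features of known-clean windows. Windows judged outliers
are discarded downstream.

Features (fixed order):

0. mean Pearson correlation of each cardiac cycle against the window's
   template cycle (cycles resampled to a common length, template = their
   pointwise mean)
1. relative dispersion of cycle peak-to-trough amplitudes
2. fraction of implausible cycle lengths (outside 300-2000 ms)
3. in-band signal fraction: spectral power in 0.7-3.5 Hz over total power
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from lonewatch.errors import DegenerateSignalError, TrainingError
from lonewatch.ppg.filtering import HIGH_HZ, LOW_HZ, bandpass
from lonewatch.ppg.peaks import detect_peaks
from lonewatch.ppg.segments import RELIABLE, UNRELIABLE, PPGWindow

N_FEATURES = 4
_CYCLE_RESAMPLE = 50
MIN_TRAINING_WINDOWS = 50


def _cycle_slices(samples: np.ndarray, peaks: np.ndarray) -> list[np.ndarray]:
    return [samples[a:b] for a, b in zip(peaks[:-1], peaks[1:]) if b - a >= 4]


def extract_morphology_features(window: PPGWindow) -> np.ndarray:
    """Fixed-length morphology feature vector for one window."""
    x = np.asarray(window.samples, dtype=float)
    if len(x) == 0 or float(np.ptp(x)) == 0.0:
        raise DegenerateSignalError("flat or empty window")
    fs = window.fs_hz

    filtered = bandpass(x, fs)
    peaks = detect_peaks(filtered, fs)
    # correlate raw cycles (filtering makes even noise self-similar)
    cycles = _cycle_slices(x, peaks) if len(peaks) >= 3 else []

    if len(cycles) >= 3:
        grid = np.linspace(0.0, 1.0, _CYCLE_RESAMPLE)
        resampled = np.stack(
            [np.interp(grid, np.linspace(0, 1, len(c)), c) for c in cycles]
        )
        # trim cycle edges: boundaries are anchored at detected peaks and
        # correlate spuriously even for noise
        trim = _CYCLE_RESAMPLE // 7
        resampled = resampled[:, trim:-trim]
        template = resampled.mean(axis=0)
        t_sd = template.std()
        corrs = []
        for row in resampled:
            if row.std() == 0 or t_sd == 0:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(row, template)[0, 1]))
        template_corr = float(np.mean(corrs))
        amps = np.array([np.ptp(c) for c in cycles])
        amp_dispersion = float(amps.std() / (amps.mean() + 1e-12))
        lengths_ms = np.diff(peaks) / fs * 1000.0
        frac_implausible = float(np.mean((lengths_ms < 300) | (lengths_ms > 2000)))
    else:
        template_corr = 0.0
        amp_dispersion = 1.0
        frac_implausible = 1.0

    freqs, psd = sp_signal.periodogram(x - x.mean(), fs=fs)
    total = float(np.trapezoid(psd, freqs)) + 1e-24
    band = (freqs >= LOW_HZ) & (freqs <= HIGH_HZ)
    inband_fraction = float(np.trapezoid(psd[band], freqs[band])) / total

    return np.array([template_corr, amp_dispersion, frac_implausible, inband_fraction])


@dataclass
class QualityModel:
    """Trained one-class SVM over window morphology features."""

    scaler: StandardScaler
    svm: OneClassSVM
    nu: float
    n_training_windows: int
    #: decision threshold calibrated so that >= 1-nu of the training
    #: windows are inliers (the SVM's own nu is only an approximate bound)
    threshold: float = 0.0
    feature_names: tuple[str, ...] = (
        "template_correlation",
        "amplitude_dispersion",
        "frac_implausible_cycles",
        "inband_fraction",
    )

    def score(self, features: np.ndarray) -> float:
        z = self.scaler.transform(np.atleast_2d(features))
        return float(self.svm.decision_function(z)[0])

    def is_reliable(self, features: np.ndarray) -> bool:
        return self.score(features) >= self.threshold


def train_quality_model(
    reliable_windows: list[PPGWindow],
    nu: float = 0.05,
    min_windows: int = MIN_TRAINING_WINDOWS,
) -> QualityModel:
    """Fit the one-class gate on windows assumed reliable.

    Raises
    ------
    TrainingError
        With fewer than ``min_windows`` training windows.
    """
    if len(reliable_windows) < min_windows:
        raise TrainingError(
            f"need >= {min_windows} training windows, got {len(reliable_windows)}"
        )
    feats = []
    for w in reliable_windows:
        f = w.quality_features
        if f is None:
            f = extract_morphology_features(w)
        feats.append(f)
    X = np.stack(feats)
    scaler = StandardScaler().fit(X)
    Xz = scaler.transform(X)
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma="scale").fit(Xz)
    scores = svm.decision_function(Xz)
    k = int(np.floor(nu * len(scores)))
    threshold = min(float(np.partition(scores, k)[k]), 0.0)
    return QualityModel(
        scaler=scaler,
        svm=svm,
        nu=nu,
        n_training_windows=len(reliable_windows),
        threshold=threshold,
    )


def assess_quality(window: PPGWindow, model: QualityModel) -> PPGWindow:
    """Set the window's reliability verdict in place and return it."""
    try:
        feats = extract_morphology_features(window)
    except DegenerateSignalError:
        window.reliability = UNRELIABLE
        return window
    window.quality_features = feats
    window.reliability = RELIABLE if model.is_reliable(feats) else UNRELIABLE
    return window
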