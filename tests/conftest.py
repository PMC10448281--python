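"""Shared fixtures: deterministic synthetic inputs built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lonewatch.datasets import (
    ALL_FEATURES,
    DaySummary,
    UCLAResponse,
)
from lonewatch.synthetic import generate_ibi_series, generate_ppg


@pytest.fixture(scope="session")
def clean_segment_60bpm():
    """Noise-free 5-minute pulse waveform at 60 bpm, 20 Hz."""
    intervals = generate_ibi_series(60.0, 0.0, duration_s=300.0, seed=0)
    return generate_ppg(intervals, fs_hz=20.0, noise_sd=0.0, seed=0)


def make_clean_windows(n, seed=0, hr_range=(55.0, 90.0), duration_s=300.0):
    """Clean synthetic 5-minute windows for quality-model training."""
    from lonewatch.ppg import window_segment

    rng = np.random.default_rng(seed)
    windows = []
    while len(windows) < n:
        hr = rng.uniform(*hr_range)
        sdnn = rng.uniform(20.0, 60.0)
        intervals = generate_ibi_series(hr, sdnn, duration_s=duration_s + 10, seed=rng)
        seg = generate_ppg(intervals, fs_hz=20.0, noise_sd=0.01, seed=rng)
        windows.extend(window_segment(seg)[:1])
    return windows[:n]


def make_artifact_windows(n, seed=0, artifact_amplitude=2.0):
    """Motion-corrupted windows: drift, noise bursts and clipping."""
    from lonewatch.ppg import window_segment

    rng = np.random.default_rng(seed)
    windows = []
    while len(windows) < n:
        hr = rng.uniform(55.0, 90.0)
        intervals = generate_ibi_series(hr, 30.0, duration_s=310, seed=rng)
        seg = generate_ppg(intervals, fs_hz=20.0, noise_sd=0.02, seed=rng)
        x = seg.samples.copy()
        t = np.arange(len(x)) / 20.0
        x += artifact_amplitude * np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t)
        burst = rng.integers(0, len(x) - 400)
        x[burst : burst + 400] += rng.normal(0, artifact_amplitude, 400)
        x = np.clip(x, None, np.quantile(x, 0.92))
        seg.samples = x
        windows.extend(window_segment(seg)[:1])
    return windows[:n]


@pytest.fixture(scope="session")
def quality_training_windows():
    return make_clean_windows(200, seed=11)


def _daily_row(day_index: int) -> dict:
    """Deterministic, hand-checkable daily feature row."""
    return {f: 100.0 + 10.0 * day_index + i for i, f in enumerate(ALL_FEATURES)}


@pytest.fixture()
def builder_fixture():
    """Five participants with known wear patterns and a frozen manifest.

    P1: 8 valid days, label 1 (social 12, boundary), imputation a no-op.
    P2: valid on the 4 oldest days only, label 0 (social 11, boundary).
    P3: 3 valid days -> excluded.
    P4: 6 valid days; one day at exactly 600 wear minutes (valid), one at
        599 (invalid); label 1.
    P5: valid sleep missing on 5 days -> 3 valid -> excluded.
    """
    end = pd.Timestamp("2021-06-08")
    window = pd.date_range(end - pd.Timedelta(days=7), end, freq="D")

    def summaries(wear, sleep_ok):
        return {
            d: DaySummary("x", d, wear_min_awake=w, has_valid_sleep=s)
            for d, w, s in zip(window, wear, sleep_ok)
        }

    full_wear = [900.0] * 8
    all_sleep = [True] * 8
    participants = {
        "P1": summaries(full_wear, all_sleep),
        "P2": summaries([900.0] * 4 + [100.0] * 4, all_sleep),
        "P3": summaries([900.0] * 3 + [0.0] * 5, all_sleep),
        "P4": summaries([900, 900, 900, 900, 600, 599, 900, 100], all_sleep),
        "P5": summaries(full_wear, [True, False, False, True, False, False, False, True]),
    }
    daily_rows = {
        pid: pd.DataFrame([_daily_row(i) for i in range(8)], index=window)
        for pid in participants
    }
    social_by_pid = {"P1": 12, "P2": 11, "P3": 18, "P4": 20, "P5": 9}
    responses = {}
    for pid, social in social_by_pid.items():
        # social item scores: social-6 distributed one point at a time
        base = [1] * 6
        rem = social - 6
        i = 0
        while rem > 0:
            if base[i % 6] < 4:
                base[i % 6] += 1
                rem -= 1
            i += 1
        responses[pid] = UCLAResponse(pid, end, tuple(base) + (1,) * 6)

    manifest = {
        "retained": ["P1", "P2", "P4"],
        "excluded": ["P3", "P5"],
        "valid_day_counts": {"P1": 8, "P2": 4, "P4": 6},
        "labels": {"P1": 1, "P2": 0, "P4": 1},
        "valid_flags": {
            "P4": [True, True, True, True, True, False, True, False],
        },
        # P2 observes days 0..3 -> per-feature mean over those 4 days
        "p2_imputed_value": {
            f: float(np.mean([_daily_row(i)[f] for i in range(4)]))
            for f in ALL_FEATURES
        },
        "dataset_shapes": {
            "sleep": (3, 6),
            "hrv": (3, 7),
            "pa": (3, 28),
            "sleep+hrv": (3, 13),
            "sleep+pa": (3, 34),
            "hrv+pa": (3, 35),
            "all": (3, 41),
        },
    }
    return {
        "daily_rows": daily_rows,
        "summaries": participants,
        "responses": responses,
        "manifest": manifest,
    }
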