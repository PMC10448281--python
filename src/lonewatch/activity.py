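"""Daily physical-activity features from 10-minute watch records.

The watch logs steps, walking/running steps, distance, active minutes
and a calorie-based intensity for every 10-minute interval it is worn.
Daily features are sums over the participant's awake time, a sedentary
minute count (awake time without walking or running activity), a
sufficient-activity indicator (daily steps strictly above 7000) and ten
distribution statistics over hourly step counts and hourly activity
duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

STEP_SUFFICIENT_THRESHOLD = 7000.0
RECORD_MIN = 10.0  # minutes per record
MIN_WORN_RECORDS_PER_HOUR = 3  # >= 30 min worn for an hour bin to count

STAT_NAMES = (
    "mean",
    "min",
    "median",
    "max",
    "sd",
    "iqr",
    "range",
    "skewness",
    "kurtosis",
    "rms",
)

SCALAR_ACTIVITY_FEATURES = (
    "step_counts",
    "walking_steps",
    "running_steps",
    "distance_m",
    "activity_duration_min",
    "activity_intensity",
    "sedentary_min",
    "sufficient_activity",
)

ACTIVITY_FEATURES = SCALAR_ACTIVITY_FEATURES + tuple(
    f"steps_{s}" for s in STAT_NAMES
) + tuple(f"duration_{s}" for s in STAT_NAMES)


@dataclass
class ActivityRecord:
    """One 10-minute interval of watch-reported activity."""

    participant_id: str
    interval_start: pd.Timestamp
    steps: float
    walking_steps: float
    running_steps: float
    distance_m: float
    active_min: float
    intensity: float


def records_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Stack records into the canonical activity DataFrame."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "interval_start": [r.interval_start for r in records],
            "steps": [r.steps for r in records],
            "walking_steps": [r.walking_steps for r in records],
            "running_steps": [r.running_steps for r in records],
            "distance_m": [r.distance_m for r in records],
            "active_min": [r.active_min for r in records],
            "intensity": [r.intensity for r in records],
        }
    )


def sufficient_activity(step_counts: float) -> bool:
    """True iff daily steps exceed 7000 (strictly)."""
    return step_counts > STEP_SUFFICIENT_THRESHOLD


def _in_intervals(ts: pd.Series, intervals: Sequence[tuple]) -> np.ndarray:
    mask = np.zeros(len(ts), dtype=bool)
    for lo, hi in intervals:
        mask |= ((ts >= lo) & (ts < hi)).to_numpy()
    return mask


def aggregate_daily(
    records: pd.DataFrame,
    awake_intervals: Sequence[tuple],
) -> Optional[dict]:
    """Sum activity over awake-time records and derive sedentary minutes.

    Parameters
    ----------
    records
        Canonical activity frame for one participant-day.
    awake_intervals
        ``(start, end)`` timestamp pairs covering the day's awake time
        (the day minus the sleep interval).

    Returns ``None`` when no record falls in the awake time (the day
    then counts as missing activity).
    """
    awake_min = sum((hi - lo).total_seconds() / 60.0 for lo, hi in awake_intervals)
    if len(records) == 0:
        return None
    mask = _in_intervals(records["interval_start"], awake_intervals)
    awake = records.loc[mask]
    if len(awake) == 0:
        return None
    moving = awake.loc[(awake["walking_steps"] > 0) | (awake["running_steps"] > 0)]
    step_counts = float(awake["steps"].sum())
    return {
        "step_counts": step_counts,
        "walking_steps": float(awake["walking_steps"].sum()),
        "running_steps": float(awake["running_steps"].sum()),
        "distance_m": float(awake["distance_m"].sum()),
        "activity_duration_min": float(awake["active_min"].sum()),
        "activity_intensity": float(awake["intensity"].sum()),
        "sedentary_min": float(awake_min - len(moving) * RECORD_MIN),
        "sufficient_activity": float(sufficient_activity(step_counts)),
    }


def hourly_series(
    records: pd.DataFrame,
    day: pd.Timestamp,
    include_all_hours: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """24-bin hourly step and active-duration series for one day.

    Each bin sums the 10-minute records inside that clock hour. Hours
    with fewer than ``MIN_WORN_RECORDS_PER_HOUR`` records are treated as
    not worn and excluded (NaN) unless ``include_all_hours``.
    """
    day = pd.Timestamp(day).normalize()
    steps = np.full(24, np.nan)
    duration = np.full(24, np.nan)
    if len(records):
        ts = pd.to_datetime(records["interval_start"])
        in_day = ((ts >= day) & (ts < day + pd.Timedelta(days=1))).to_numpy()
        hours = ts.dt.hour.to_numpy()[in_day]
        step_vals = records["steps"].to_numpy(dtype=float)[in_day]
        dur_vals = records["active_min"].to_numpy(dtype=float)[in_day]
        counts = np.bincount(hours, minlength=24)
        step_sums = np.bincount(hours, weights=step_vals, minlength=24)
        dur_sums = np.bincount(hours, weights=dur_vals, minlength=24)
        worn = (counts >= MIN_WORN_RECORDS_PER_HOUR) | (include_all_hours & (counts > 0))
        steps[worn] = step_sums[worn]
        duration[worn] = dur_sums[worn]
    if include_all_hours:
        steps = np.nan_to_num(steps)
        duration = np.nan_to_num(duration)
    return steps, duration


def distribution_stats(values: np.ndarray) -> Optional[dict]:
    """Ten distribution statistics over the included (non-NaN) bins.

    Skewness and excess kurtosis use biased sample moments and are
    defined as 0 for a zero-variance series. Fewer than two included
    bins yield ``None`` (all ten statistics missing).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return None
    sd = float(np.std(v))
    if sd == 0.0:
        skew, kurt = 0.0, 0.0
    else:
        skew = float(sp_stats.skew(v, bias=True))
        kurt = float(sp_stats.kurtosis(v, fisher=True, bias=True))
    q75, q25 = np.percentile(v, [75, 25])
    return {
        "mean": float(np.mean(v)),
        "min": float(np.min(v)),
        "median": float(np.median(v)),
        "max": float(np.max(v)),
        "sd": sd,
        "iqr": float(q75 - q25),
        "range": float(np.max(v) - np.min(v)),
        "skewness": skew,
        "kurtosis": kurt,
        "rms": float(np.sqrt(np.mean(v**2))),
    }


def derive_activity_row(
    records: pd.DataFrame,
    day: pd.Timestamp,
    awake_intervals: Sequence[tuple],
    include_all_hours: bool = False,
) -> Optional[dict]:
    """Full daily activity feature sub-row, or ``None`` when missing."""
    agg = aggregate_daily(records, awake_intervals)
    if agg is None:
        return None
    steps_h, dur_h = hourly_series(records, day, include_all_hours=include_all_hours)
    row = dict(agg)
    for prefix, series in (("steps", steps_h), ("duration", dur_h)):
        stats = distribution_stats(series)
        for name in STAT_NAMES:
            row[f"{prefix}_{name}"] = np.nan if stats is None else stats[name]
    return row
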