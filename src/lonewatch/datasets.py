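"""Labeled 8-day samples and the seven feature-set datasets.

Each questionnaire response anchors one sample: the response day plus
the 7 preceding days. A day is valid when the watch was worn at least
10 hours during waking time and collected valid sleep data; samples with
fewer than 4 valid days are discarded. Remaining missing daily values
are filled with the within-sample mean of that feature, the 8 daily rows
collapse to one vector (mean by default), and the loneliness label is 1
iff the social factor of the 12-item questionnaire scores at least 12.

Seven datasets are assembled — every non-empty combination of the HRV,
sleep and physical-activity feature groups — with identical sample order
and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lonewatch.activity import ACTIVITY_FEATURES
from lonewatch.errors import BuildError, ParameterError
from lonewatch.hrv import HRV_FEATURES
from lonewatch.sleep import SLEEP_FEATURES

WEAR_MIN_AWAKE_THRESHOLD = 600.0  # >= 10 h awake wear
MIN_VALID_DAYS = 4
WINDOW_DAYS = 8
LONELINESS_SOCIAL_CUTOFF = 12

#: default item -> factor mapping (items 1-6 social, 7-12 emotional);
#: the published instrument's exact assignment is configurable.
DEFAULT_SOCIAL_ITEMS = (0, 1, 2, 3, 4, 5)

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "hrv": tuple(HRV_FEATURES),
    "sleep": tuple(SLEEP_FEATURES),
    "pa": tuple(ACTIVITY_FEATURES),
}

DATASET_NAMES = ("sleep", "hrv", "pa", "sleep+hrv", "sleep+pa", "hrv+pa", "all")

_DATASET_GROUPS: dict[str, tuple[str, ...]] = {
    "sleep": ("sleep",),
    "hrv": ("hrv",),
    "pa": ("pa",),
    "sleep+hrv": ("sleep", "hrv"),
    "sleep+pa": ("sleep", "pa"),
    "hrv+pa": ("hrv", "pa"),
    "all": ("sleep", "hrv", "pa"),
}

ALL_FEATURES = tuple(
    f for g in ("hrv", "sleep", "pa") for f in FEATURE_GROUPS[g]
)


@dataclass
class UCLAResponse:
    """One 12-item questionnaire response."""

    participant_id: str
    date: pd.Timestamp
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 12:
            raise ParameterError("expected 12 item scores")


@dataclass
class DaySummary:
    """Wear and sleep-validity summary used by the valid-day rule."""

    participant_id: str
    date: pd.Timestamp
    wear_min_awake: float
    has_valid_sleep: bool

    @property
    def valid(self) -> bool:
        return is_valid_day(self.wear_min_awake, self.has_valid_sleep)


@dataclass
class DataSample:
    """One labeled 8-day observation."""

    participant_id: str
    response_date: pd.Timestamp
    days: pd.DataFrame  # 8 rows x features, NaN where missing
    valid_day_count: int
    label: int
    social_score: int
    emotional_score: int
    missing_features: tuple[str, ...] = ()
    vector: Optional[pd.Series] = field(default=None, repr=False)


@dataclass
class FeatureDataset:
    """Sample x feature matrix plus labels for one feature combination."""

    name: str
    X: pd.DataFrame
    y: np.ndarray
    participants: np.ndarray
    feature_names: tuple[str, ...]


def score_ucla(
    items: Sequence[int],
    social_items: Sequence[int] = DEFAULT_SOCIAL_ITEMS,
) -> tuple[int, int]:
    """(social_score, emotional_score): each factor sums its 6 items."""
    if len(items) != 12:
        raise ParameterError("expected 12 item scores")
    social_idx = set(social_items)
    if len(social_idx) != 6:
        raise ParameterError("social factor must have exactly 6 items")
    social = sum(items[i] for i in social_idx)
    emotional = sum(items[i] for i in range(12) if i not in social_idx)
    return int(social), int(emotional)


def label(social_score: int) -> int:
    """1 (loneliness) iff the social score is at least 12."""
    if not 6 <= social_score <= 24:
        raise ParameterError(f"social score {social_score} outside [6, 24]")
    return int(social_score >= LONELINESS_SOCIAL_CUTOFF)


def is_valid_day(wear_min_awake: float, has_valid_sleep: bool) -> bool:
    """Valid day: >= 600 awake wear minutes and valid sleep data."""
    return wear_min_awake >= WEAR_MIN_AWAKE_THRESHOLD and bool(has_valid_sleep)


def build_sample(
    response: UCLAResponse,
    daily_rows: pd.DataFrame,
    day_summaries: dict[pd.Timestamp, DaySummary],
    social_items: Sequence[int] = DEFAULT_SOCIAL_ITEMS,
    min_valid_days: int = MIN_VALID_DAYS,
) -> Optional[DataSample]:
    """Assemble one sample from the response day and the 7 days before.

    ``daily_rows`` is indexed by date with one column per feature.
    Invalid days contribute all-NaN rows. Returns ``None`` when fewer
    than ``min_valid_days`` of the 8 days are valid.
    """
    end = pd.Timestamp(response.date).normalize()
    window = pd.date_range(end - pd.Timedelta(days=WINDOW_DAYS - 1), end, freq="D")
    valid = np.array(
        [
            day_summaries.get(d) is not None and day_summaries[d].valid
            for d in window
        ]
    )
    valid_count = int(valid.sum())
    if valid_count < min_valid_days:
        return None
    rows = (
        daily_rows.reindex(index=window)
        .reindex(columns=list(ALL_FEATURES))
        .astype(float)
    )
    rows.loc[~valid] = np.nan
    social, emotional = score_ucla(response.items, social_items)
    return DataSample(
        participant_id=response.participant_id,
        response_date=end,
        days=rows,
        valid_day_count=valid_count,
        label=label(social),
        social_score=social,
        emotional_score=emotional,
    )


def impute(sample: DataSample) -> DataSample:
    """Fill each feature's missing days with its within-sample mean.

    Features observed on no day at all are flagged in
    ``missing_features``; datasets requiring them drop the sample.
    """
    days = sample.days.copy()
    missing = []
    for col in days.columns:
        observed = days[col].dropna()
        if len(observed) == 0:
            missing.append(col)
        elif len(observed) < len(days):
            days[col] = days[col].fillna(observed.mean())
    sample.days = days
    sample.missing_features = tuple(missing)
    return sample


def collapse(sample: DataSample, mode: str = "mean") -> DataSample:
    """Collapse the 8 daily rows into the sample's feature vector.

    ``mode="mean"`` averages over days (default); ``mode="concat"``
    concatenates the 8 rows (vector length 8 x features).
    """
    if mode == "mean":
        sample.vector = sample.days.mean(axis=0)
    elif mode == "concat":
        parts = {}
        for d, (_, row) in enumerate(sample.days.iterrows()):
            for col, val in row.items():
                parts[f"{col}_d{d}"] = val
        sample.vector = pd.Series(parts)
    else:
        raise ParameterError(f"unknown collapse mode {mode!r}")
    return sample


def assemble(
    samples: Sequence[DataSample],
    collapse_mode: str = "mean",
) -> dict[str, FeatureDataset]:
    """Build the seven feature-combination datasets from retained samples."""
    if len(samples) == 0:
        raise BuildError("no retained samples")
    for s in samples:
        if s.vector is None:
            impute(s)
            collapse(s, collapse_mode)
    out: dict[str, FeatureDataset] = {}
    for name in DATASET_NAMES:
        cols: list[str] = []
        for g in _DATASET_GROUPS[name]:
            cols.extend(FEATURE_GROUPS[g])
        keep = [
            s
            for s in samples
            if not any(f in cols for f in s.missing_features)
        ]
        if not keep:
            raise BuildError(f"no samples usable for dataset {name!r}")
        if collapse_mode == "concat":
            use_cols = [
                c for c in keep[0].vector.index if c.rsplit("_d", 1)[0] in cols
            ]
        else:
            use_cols = cols
        X = pd.DataFrame(
            [s.vector[use_cols] for s in keep],
            index=[f"{s.participant_id}@{s.response_date.date()}" for s in keep],
        )
        out[name] = FeatureDataset(
            name=name,
            X=X,
            y=np.array([s.label for s in keep], dtype=int),
            participants=np.array([s.participant_id for s in keep]),
            feature_names=tuple(use_cols),
        )
    return out


def activity_columns(dataset: FeatureDataset) -> list[str]:
    """Columns of a dataset that belong to the physical-activity group."""
    pa = set(FEATURE_GROUPS["pa"])
    return [
        c
        for c in dataset.X.columns
        if c in pa or (isinstance(c, str) and c.rsplit("_d", 1)[0] in pa)
    ]
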