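"""End-to-end orchestration: bundles -> daily rows -> datasets -> reports."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lonewatch import activity as activity_mod
from lonewatch import datasets as ds
from lonewatch import hrv as hrv_mod
from lonewatch import sleep as sleep_mod
from lonewatch.modeling import EvaluationReport, ModelSpec, lopo_evaluate
from lonewatch.ppg.cleaning import clean_ibis, clean_intervals
from lonewatch.ppg.filtering import bandpass
from lonewatch.ppg.peaks import detect_peaks
from lonewatch.ppg.quality import QualityModel, assess_quality
from lonewatch.ppg.segments import RELIABLE, window_segment
from lonewatch.synthetic.cohort import ParticipantBundle

_DEFAULT_BEDTIME_H = 23


def _awake_intervals(
    date: pd.Timestamp,
    nights_by_date: dict,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Awake time for a day: from that morning's sleep offset until the
    next night's onset (or a 23:00 default when the next night is absent)."""
    night = nights_by_date.get(date)
    if night is None:
        return []
    next_night = nights_by_date.get(date + pd.Timedelta(days=1))
    end = (
        next_night.sleep_onset
        if next_night is not None
        else date + pd.Timedelta(hours=_DEFAULT_BEDTIME_H)
    )
    start = night.sleep_offset
    if end <= start:
        return []
    return [(start, end)]


def _usable_ibis(
    bundle: ParticipantBundle,
    quality_model: Optional[QualityModel],
) -> list[tuple[pd.Timestamp, object, float]]:
    """(window_start, cleaned IBIs, hr) for every usable window.

    The full HRV record (including the spectral estimate) is computed
    later and only for the window actually selected as resting.
    """
    out = []
    if bundle.ibi_windows:
        for w in bundle.ibi_windows:
            ibis = clean_intervals(w.intervals)
            if ibis.usable:
                out.append((w.start_time, ibis, hrv_mod.compute_hr(ibis)))
        return out
    for seg in bundle.ppg_segments:
        for win in window_segment(seg):
            if quality_model is not None:
                assess_quality(win, quality_model)
                if win.reliability != RELIABLE:
                    continue
            filtered = bandpass(win.samples, win.fs_hz)
            peaks = detect_peaks(filtered, win.fs_hz)
            ibis = clean_ibis(peaks, win.fs_hz)
            if ibis.usable:
                out.append((win.start_time, ibis, hrv_mod.compute_hr(ibis)))
    return out


def extract_participant_daily(
    bundle: ParticipantBundle,
    quality_model: Optional[QualityModel] = None,
    spectral_method: str = "lomb",
) -> tuple[pd.DataFrame, dict]:
    """Daily feature rows and day summaries for one participant.

    Returns ``(daily_rows, day_summaries)`` where ``daily_rows`` is
    indexed by normalized date and ``day_summaries`` maps dates to
    :class:`~lonewatch.datasets.DaySummary`.
    """
    nights_by_date = {pd.Timestamp(n.date).normalize(): n for n in bundle.sleep_nights}
    usable = _usable_ibis(bundle, quality_model)

    rows: dict[pd.Timestamp, dict] = {}
    summaries: dict[pd.Timestamp, ds.DaySummary] = {}
    records = bundle.activity_records
    for date, night in sorted(nights_by_date.items()):
        row: dict = {}
        sleep_row = sleep_mod.derive_sleep_row(night)
        if sleep_row is not None:
            row.update(sleep_row)

        candidates = [
            (start, ibis, hr)
            for start, ibis, hr in usable
            if night.sleep_onset <= start <= night.sleep_offset and np.isfinite(hr)
        ]
        if candidates:
            start, ibis, _ = min(candidates, key=lambda c: (c[2], c[0]))
            rec = hrv_mod.compute_hrv_record(
                ibis, window_start=start, method=spectral_method
            )
            if rec is not None:
                row.update(rec.as_dict())

        awake = _awake_intervals(date, nights_by_date)
        wear_min = 0.0
        if awake and len(records):
            mask = activity_mod._in_intervals(records["interval_start"], awake)
            wear_min = float(mask.sum()) * activity_mod.RECORD_MIN
            act_row = activity_mod.derive_activity_row(
                records.loc[mask], date, awake
            )
            if act_row is not None:
                row.update(act_row)
        rows[date] = row
        summaries[date] = ds.DaySummary(
            participant_id=bundle.participant_id,
            date=date,
            wear_min_awake=wear_min,
            has_valid_sleep=night.valid,
        )
    daily = pd.DataFrame.from_dict(rows, orient="index")
    return daily, summaries


def build_cohort_samples(
    bundles: Sequence[ParticipantBundle],
    quality_model: Optional[QualityModel] = None,
    spectral_method: str = "lomb",
    social_items: Sequence[int] = ds.DEFAULT_SOCIAL_ITEMS,
) -> tuple[list[ds.DataSample], list[dict]]:
    """All retained samples across the cohort, plus an exclusion log."""
    samples: list[ds.DataSample] = []
    exclusions: list[dict] = []
    for bundle in bundles:
        daily, summaries = extract_participant_daily(
            bundle, quality_model=quality_model, spectral_method=spectral_method
        )
        for resp in bundle.ucla_responses:
            sample = ds.build_sample(resp, daily, summaries, social_items=social_items)
            if sample is None:
                exclusions.append(
                    {
                        "participant_id": bundle.participant_id,
                        "response_date": str(pd.Timestamp(resp.date).date()),
                        "reason": "fewer_than_4_valid_days",
                    }
                )
            else:
                samples.append(sample)
    return samples, exclusions


def build_cohort_datasets(
    bundles: Sequence[ParticipantBundle],
    collapse_mode: str = "mean",
    **kwargs,
) -> dict[str, ds.FeatureDataset]:
    samples, _ = build_cohort_samples(bundles, **kwargs)
    return ds.assemble(samples, collapse_mode=collapse_mode)


def evaluate_datasets(
    datasets: dict[str, ds.FeatureDataset],
    model_kinds: Sequence[str] = ("decision_tree", "gradient_boosting"),
    rfe_k: Optional[int] = 10,
    seed: int = 0,
    dataset_names: Optional[Sequence[str]] = None,
    rfe_ranking_hyperparameters: Optional[dict] = None,
) -> list[EvaluationReport]:
    """Evaluate the requested models on the requested datasets.

    ``rfe_ranking_hyperparameters`` optionally overrides hyperparameters
    of the estimator used for RFE importance ranking only (e.g. fewer
    boosting rounds on tight compute budgets); fold models are untouched.
    """
    names = list(dataset_names) if dataset_names else list(datasets)
    reports = []
    for name in names:
        for kind in model_kinds:
            spec = ModelSpec(kind=kind, seed=seed)
            rfe_spec = None
            if rfe_ranking_hyperparameters and spec.kind == "gradient_boosting":
                rfe_spec = ModelSpec(
                    kind=kind, seed=seed,
                    hyperparameters=dict(rfe_ranking_hyperparameters),
                )
            reports.append(
                lopo_evaluate(
                    datasets[name],
                    spec,
                    rfe_k=rfe_k,
                    export_tree=(spec.kind == "decision_tree"),
                    rfe_spec=rfe_spec,
                )
            )
    return reports
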