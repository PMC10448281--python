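"""Full synthetic participant bundles with planted class effects.

Every participant gets two questionnaire time points (emulating late
pregnancy and three months postpartum), each anchoring an 8-day window
of sleep nights, 10-minute activity records and nightly PPG (or, in
``fast_mode``, pre-extracted interbeat-interval windows). Participants
assigned the lonely class get scaled-down activity intensity, a flatter
hourly step profile and lower resting SDNN — the discriminative
directions the downstream models should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from lonewatch.datasets import UCLAResponse
from lonewatch.errors import ConfigurationError
from lonewatch.ppg.segments import PPGSegment
from lonewatch.sleep import SleepNight
from lonewatch.synthetic.ibi import generate_ibi_series
from lonewatch.synthetic.ppg import generate_ppg

DEFAULT_EFFECTS = {
    "activity_intensity": 0.6,
    "step_kurtosis_shift": 0.35,
    "resting_sdnn": 0.8,
}

WINDOW_DAYS = 8
#: questionnaire response days relative to the cohort start date
RESPONSE_DAY_OFFSETS = (7, 37)
NIGHT_WINDOWS_FAST = 4
ACTIVITY_COLUMNS = (
    "participant_id",
    "interval_start",
    "steps",
    "walking_steps",
    "running_steps",
    "distance_m",
    "active_min",
    "intensity",
)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; same seed means identical output."""

    n_participants: int = 40
    loneliness_prevalence: float = 0.4
    effect_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    missing_day_rate: float = 0.0
    ppg_noise_sd: float = 0.05
    fast_mode: bool = False
    seed: int = 0
    segments_per_day: int = 12  # every other hour
    start_date: str = "2021-03-01"

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if not 0.0 <= self.loneliness_prevalence <= 1.0:
            raise ConfigurationError("loneliness_prevalence outside [0, 1]")
        if not 0.0 <= self.missing_day_rate <= 1.0:
            raise ConfigurationError("missing_day_rate outside [0, 1]")
        if self.ppg_noise_sd < 0:
            raise ConfigurationError("ppg_noise_sd must be nonnegative")
        effects = dict(DEFAULT_EFFECTS)
        effects.update(self.effect_multipliers)
        self.effect_multipliers = effects

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class IBIWindow:
    """A pre-extracted interval window (fast_mode shortcut)."""

    participant_id: str
    start_time: pd.Timestamp
    intervals: np.ndarray


@dataclass
class ParticipantBundle:
    """Everything one participant contributes, plus the ground truth."""

    participant_id: str
    true_label: int
    ppg_segments: list[PPGSegment]
    ibi_windows: list[IBIWindow]
    sleep_nights: list[SleepNight]
    activity_records: pd.DataFrame
    ucla_responses: list[UCLAResponse]
    ground_truth: dict


def _partition_score(total: int, n_items: int, lo: int, hi: int, rng) -> tuple[int, ...]:
    """Random item scores in [lo, hi] summing to ``total``."""
    items = np.full(n_items, lo)
    remaining = total - n_items * lo
    while remaining > 0:
        open_idx = np.flatnonzero(items < hi)
        items[rng.choice(open_idx)] += 1
        remaining -= 1
    return tuple(int(v) for v in items)


def _hourly_profile(flatten: float) -> np.ndarray:
    """Awake-hour step weights (hours 7..22), optionally mixed toward uniform."""
    hours = np.arange(7, 23)
    peaked = np.exp(-0.5 * ((hours - 13.0) / 3.0) ** 2) + 0.15
    peaked = peaked / peaked.sum()
    uniform = np.full(len(hours), 1.0 / len(hours))
    return (1.0 - flatten) * peaked + flatten * uniform


def _generate_day(
    pid: str,
    date: pd.Timestamp,
    params: dict,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> dict:
    """All streams for one participant-day."""
    onset = date - pd.Timedelta(hours=1) + pd.Timedelta(minutes=float(rng.normal(0, 20)))
    offset = date + pd.Timedelta(hours=6, minutes=45) + pd.Timedelta(
        minutes=float(rng.normal(0, 25))
    )
    interval_min = (offset - onset).total_seconds() / 60.0
    waso = float(min(rng.exponential(12.0), 0.3 * interval_min))
    night = SleepNight(
        participant_id=pid,
        date=date,
        tst=interval_min - waso,
        fragmentation=int(rng.poisson(2.0)),
        waso=waso,
        avg_hand_movement=float(rng.uniform(0.1, 0.5)),
        sleep_onset=onset,
        sleep_offset=offset,
        valid=True,
    )

    # activity: 10-min records from wake until ~23:00; the day's intensity
    # budget is distributed over records proportionally to steps, so the
    # class intensity multiplier is not drowned by step-count variance
    total_steps = max(float(rng.normal(params["daily_steps"], 1200.0)), 500.0)
    daily_intensity = max(float(rng.normal(params["daily_intensity"], 80.0)), 50.0)
    hourly_weights = _hourly_profile(params["flatten"])
    hourly_steps = np.zeros(24)
    records = []
    for h, w in zip(range(7, 23), hourly_weights):
        h_steps = max(total_steps * w * (1.0 + float(rng.normal(0, 0.15))), 0.0)
        hourly_steps[h] = h_steps
        slot_weights = rng.dirichlet(np.ones(6) * 4.0)
        for slot in range(6):
            ts = date + pd.Timedelta(hours=h, minutes=10 * slot)
            if ts < offset:  # still asleep
                hourly_steps[h] -= h_steps * slot_weights[slot]
                continue
            steps = h_steps * slot_weights[slot]
            running = steps * float(rng.uniform(0, 0.05))
            records.append(
                {
                    "participant_id": pid,
                    "interval_start": ts,
                    "steps": steps,
                    "walking_steps": steps - running,
                    "running_steps": running,
                    "distance_m": steps * 0.7,
                    "active_min": min(steps / 80.0, 10.0),
                    "intensity": daily_intensity * steps / total_steps,
                }
            )

    # nightly PPG / IBI windows inside the sleep interval
    night_hrs = params["night_hr"] + rng.uniform(0.0, 8.0, NIGHT_WINDOWS_FAST)
    resting_idx = int(np.argmin(night_hrs))
    window_starts = [
        onset + pd.Timedelta(minutes=45 + 90 * i) for i in range(NIGHT_WINDOWS_FAST)
    ]
    segments: list[PPGSegment] = []
    ibi_windows: list[IBIWindow] = []
    true_resting = {}
    for i, (hr, ws) in enumerate(zip(night_hrs, window_starts)):
        sdnn = params["resting_sdnn"] * (1.0 + float(rng.normal(0, 0.06)))
        intervals = generate_ibi_series(
            mean_hr_bpm=float(hr),
            sdnn_target_ms=max(sdnn, 5.0),
            modulation_hz=0.1,
            duration_s=330.0 if cfg.fast_mode else 720.0,
            seed=rng,
        )
        if i == resting_idx:
            true_resting = {
                "true_resting_hr_bpm": float(hr),
                "true_resting_mean_ibi_ms": float(np.mean(intervals)),
                "true_resting_sdnn_ms": float(np.std(intervals)),
            }
        if cfg.fast_mode:
            ibi_windows.append(
                IBIWindow(participant_id=pid, start_time=ws, intervals=intervals)
            )
        else:
            segments.append(
                generate_ppg(
                    intervals,
                    fs_hz=20.0,
                    noise_sd=cfg.ppg_noise_sd,
                    seed=rng,
                    participant_id=pid,
                    start_time=ws,
                )
            )
    if not cfg.fast_mode:
        # daytime segments every other hour (unused by resting features but
        # part of the emitted stream)
        n_day_segments = max(cfg.segments_per_day - NIGHT_WINDOWS_FAST, 0)
        day_hours = np.linspace(8, 22, n_day_segments, endpoint=False) if n_day_segments else []
        for h in day_hours:
            hr = params["night_hr"] + 15.0 + float(rng.normal(0, 3))
            intervals = generate_ibi_series(
                mean_hr_bpm=hr,
                sdnn_target_ms=max(params["resting_sdnn"] * 0.8, 5.0),
                modulation_hz=0.1,
                duration_s=720.0,
                seed=rng,
            )
            segments.append(
                generate_ppg(
                    intervals,
                    fs_hz=20.0,
                    noise_sd=cfg.ppg_noise_sd,
                    seed=rng,
                    participant_id=pid,
                    start_time=date + pd.Timedelta(hours=float(h)),
                )
            )

    return {
        "night": night,
        "records": records,
        "segments": segments,
        "ibi_windows": ibi_windows,
        "truth": {
            **true_resting,
            "hourly_steps": [float(v) for v in hourly_steps],
        },
    }


def _generate_participant(
    pid: str, lonely: bool, cfg: CohortConfig, seed_seq: np.random.SeedSequence
) -> ParticipantBundle:
    rng = np.random.default_rng(seed_seq)
    eff = cfg.effect_multipliers
    params = {
        "night_hr": float(rng.uniform(56.0, 72.0)),
        "resting_sdnn": float(np.clip(rng.normal(55.0, 8.0), 25.0, 120.0)),
        "daily_steps": float(rng.normal(9000.0, 1500.0)),
        "daily_intensity": float(rng.normal(1200.0, 120.0)),
        "flatten": 0.0,
    }
    if lonely:
        params["resting_sdnn"] *= eff["resting_sdnn"]
        params["daily_intensity"] *= eff["activity_intensity"]
        params["flatten"] = eff["step_kurtosis_shift"]

    start = pd.Timestamp(cfg.start_date)
    nights, records, segments, ibi_windows = [], [], [], []
    truth_days = {}
    responses = []
    for resp_offset in RESPONSE_DAY_OFFSETS:
        resp_date = start + pd.Timedelta(days=resp_offset)
        for back in range(WINDOW_DAYS - 1, -1, -1):
            date = resp_date - pd.Timedelta(days=back)
            day = _generate_day(pid, date, params, cfg, rng)
            nights.append(day["night"])
            records.extend(day["records"])
            segments.extend(day["segments"])
            ibi_windows.extend(day["ibi_windows"])
            truth_days[str(date.date())] = day["truth"]

        if lonely:
            social = int(rng.integers(13, 23))
        else:
            social = int(rng.integers(6, 12))
        emotional = int(rng.integers(6, 13))
        items = _partition_score(social, 6, 1, 4, rng) + _partition_score(
            emotional, 6, 1, 4, rng
        )
        responses.append(
            UCLAResponse(participant_id=pid, date=resp_date, items=items)
        )

    frame = (
        pd.DataFrame(records, columns=list(ACTIVITY_COLUMNS))
        if records
        else pd.DataFrame(columns=list(ACTIVITY_COLUMNS))
    )
    return ParticipantBundle(
        participant_id=pid,
        true_label=int(lonely),
        ppg_segments=segments,
        ibi_windows=ibi_windows,
        sleep_nights=nights,
        activity_records=frame,
        ucla_responses=responses,
        ground_truth={
            "label": int(lonely),
            "params": params,
            "dropped_days": [],
            "days": truth_days,
        },
    )


def inject_missingness(
    bundle: ParticipantBundle,
    missing_day_rate: float,
    seed: int | np.random.Generator = 0,
) -> ParticipantBundle:
    """Drop whole days (all streams) independently with the given rate.

    Dropped dates are appended to ``ground_truth["dropped_days"]``.
    """
    if not 0.0 <= missing_day_rate <= 1.0:
        raise ConfigurationError("missing_day_rate outside [0, 1]")
    if missing_day_rate == 0.0:
        return bundle
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = sorted({n.date for n in bundle.sleep_nights})
    dropped = {d for d in days if rng.random() < missing_day_rate}
    if not dropped:
        return bundle

    # night windows start before midnight: attribute timestamps inside a
    # sleep interval to that night's date, otherwise to the calendar date
    night_intervals = [
        (n.sleep_onset, n.sleep_offset, n.date) for n in bundle.sleep_nights
    ]

    def day_of(ts: pd.Timestamp) -> pd.Timestamp:
        ts = pd.Timestamp(ts)
        for onset, offset, date in night_intervals:
            if onset <= ts <= offset:
                return date
        return ts.normalize()

    bundle.sleep_nights = [n for n in bundle.sleep_nights if n.date not in dropped]
    bundle.ppg_segments = [
        s for s in bundle.ppg_segments if day_of(s.start_time) not in dropped
    ]
    bundle.ibi_windows = [
        w for w in bundle.ibi_windows if day_of(w.start_time) not in dropped
    ]
    if len(bundle.activity_records):
        keep = ~bundle.activity_records["interval_start"].map(day_of).isin(dropped)
        bundle.activity_records = bundle.activity_records.loc[keep].reset_index(
            drop=True
        )
    bundle.ground_truth["dropped_days"].extend(
        sorted(str(d.date()) for d in dropped)
    )
    return bundle


def generate_cohort(config: CohortConfig) -> list[ParticipantBundle]:
    """Generate the whole cohort; deterministic in ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    n_lonely = int(round(config.n_participants * config.loneliness_prevalence))
    order = label_rng.permutation(config.n_participants)
    lonely_ids = set(order[:n_lonely])

    child_seqs = root.spawn(config.n_participants + 1)[1:]
    bundles = []
    for i, seq in enumerate(child_seqs):
        pid = f"P{i + 1:03d}"
        bundle = _generate_participant(pid, i in lonely_ids, config, seq)
        miss_rng = np.random.default_rng(seq.spawn(1)[0])
        bundle = inject_missingness(bundle, config.missing_day_rate, miss_rng)
        bundles.append(bundle)
    return bundles
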