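"""Plain-text serialization of the pipeline's streams.

Schemas
-------
``ppg.csv``
    participant_id, timestamp_iso8601, amplitude — segment boundaries
    are inferred from gaps of at least 60 s.
``ibi.csv``
    participant_id, window_start, beat_index, interval_ms (fast mode).
``sleep.csv``
    participant_id, date, sleep_onset, sleep_offset, tst_min,
    fragmentation, waso_min, avg_hand_movement, valid.
``activity.csv``
    participant_id, interval_start, steps, walking_steps, running_steps,
    distance_m, active_min, intensity.
``ucla.csv``
    participant_id, date, item_1..item_12.
``ground_truth.json``
    per-participant planted labels, parameters and dropped days.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lonewatch.datasets import UCLAResponse
from lonewatch.ppg.segments import PPGSegment
from lonewatch.sleep import SleepNight
from lonewatch.synthetic.cohort import ACTIVITY_COLUMNS, IBIWindow, ParticipantBundle

SEGMENT_GAP_S = 60.0


def write_cohort(
    bundles: Sequence[ParticipantBundle], outdir, write_ppg: bool = True
) -> None:
    """Write all cohort streams as CSV plus the ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sleep_rows, ucla_rows, ibi_rows, ppg_rows = [], [], [], []
    activity_frames = []
    truth = {}
    for b in bundles:
        truth[b.participant_id] = b.ground_truth
        for n in b.sleep_nights:
            sleep_rows.append(
                {
                    "participant_id": n.participant_id,
                    "date": str(pd.Timestamp(n.date).date()),
                    "sleep_onset": n.sleep_onset.isoformat(),
                    "sleep_offset": n.sleep_offset.isoformat(),
                    "tst_min": n.tst,
                    "fragmentation": n.fragmentation,
                    "waso_min": n.waso,
                    "avg_hand_movement": n.avg_hand_movement,
                    "valid": int(n.valid),
                }
            )
        for r in b.ucla_responses:
            row = {
                "participant_id": r.participant_id,
                "date": str(pd.Timestamp(r.date).date()),
            }
            row.update({f"item_{i + 1}": v for i, v in enumerate(r.items)})
            ucla_rows.append(row)
        for w in b.ibi_windows:
            for i, ibi in enumerate(w.intervals):
                ibi_rows.append(
                    {
                        "participant_id": w.participant_id,
                        "window_start": w.start_time.isoformat(),
                        "beat_index": i,
                        "interval_ms": float(ibi),
                    }
                )
        if write_ppg:
            for seg in b.ppg_segments:
                ts = seg.start_time + pd.to_timedelta(
                    np.arange(len(seg.samples)) / seg.fs_hz, unit="s"
                )
                ppg_rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": seg.participant_id,
                            "timestamp_iso8601": ts,
                            "amplitude": seg.samples,
                        }
                    )
                )
        activity_frames.append(b.activity_records)

    pd.DataFrame(sleep_rows).to_csv(outdir / "sleep.csv", index=False)
    pd.DataFrame(ucla_rows).to_csv(outdir / "ucla.csv", index=False)
    pd.concat(activity_frames, ignore_index=True).to_csv(
        outdir / "activity.csv", index=False
    )
    if ibi_rows:
        pd.DataFrame(ibi_rows).to_csv(outdir / "ibi.csv", index=False)
    if write_ppg and ppg_rows:
        pd.concat(ppg_rows, ignore_index=True).to_csv(outdir / "ppg.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_ppg_csv(path, fs_hz: float = 20.0) -> list[PPGSegment]:
    """Parse a PPG CSV into segments, splitting on >= 60 s gaps."""
    df = pd.read_csv(path, parse_dates=["timestamp_iso8601"])
    segments = []
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("timestamp_iso8601")
        gaps = sub["timestamp_iso8601"].diff().dt.total_seconds().fillna(0.0)
        seg_id = (gaps >= SEGMENT_GAP_S).cumsum()
        for _, chunk in sub.groupby(seg_id):
            segments.append(
                PPGSegment(
                    participant_id=str(pid),
                    start_time=chunk["timestamp_iso8601"].iloc[0],
                    fs_hz=fs_hz,
                    samples=chunk["amplitude"].to_numpy(),
                )
            )
    return segments


def read_sleep_csv(path) -> list[SleepNight]:
    df = pd.read_csv(path, parse_dates=["date", "sleep_onset", "sleep_offset"])
    return [
        SleepNight(
            participant_id=str(r.participant_id),
            date=pd.Timestamp(r.date).normalize(),
            tst=float(r.tst_min),
            fragmentation=int(r.fragmentation),
            waso=float(r.waso_min),
            avg_hand_movement=float(r.avg_hand_movement),
            sleep_onset=r.sleep_onset,
            sleep_offset=r.sleep_offset,
            valid=bool(r.valid),
        )
        for r in df.itertuples()
    ]


def read_activity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["interval_start"])
    return df[list(ACTIVITY_COLUMNS)]


def read_ucla_csv(path) -> list[UCLAResponse]:
    df = pd.read_csv(path, parse_dates=["date"])
    items_cols = [f"item_{i + 1}" for i in range(12)]
    return [
        UCLAResponse(
            participant_id=str(r["participant_id"]),
            date=pd.Timestamp(r["date"]),
            items=tuple(int(r[c]) for c in items_cols),
        )
        for _, r in df.iterrows()
    ]


def read_ibi_csv(path) -> list[IBIWindow]:
    df = pd.read_csv(path, parse_dates=["window_start"])
    windows = []
    for (pid, start), sub in df.groupby(["participant_id", "window_start"], sort=True):
        sub = sub.sort_values("beat_index")
        windows.append(
            IBIWindow(
                participant_id=str(pid),
                start_time=pd.Timestamp(start),
                intervals=sub["interval_ms"].to_numpy(),
            )
        )
    return windows


def read_cohort(indir, fs_hz: float = 20.0) -> list[ParticipantBundle]:
    """Rebuild participant bundles from a cohort directory."""
    indir = Path(indir)
    nights = read_sleep_csv(indir / "sleep.csv")
    records = read_activity_csv(indir / "activity.csv")
    responses = read_ucla_csv(indir / "ucla.csv")
    segments = (
        read_ppg_csv(indir / "ppg.csv", fs_hz=fs_hz)
        if (indir / "ppg.csv").exists()
        else []
    )
    ibi_windows = (
        read_ibi_csv(indir / "ibi.csv") if (indir / "ibi.csv").exists() else []
    )
    truth = {}
    if (indir / "ground_truth.json").exists():
        with open(indir / "ground_truth.json") as fh:
            truth = json.load(fh)

    pids = sorted(
        {n.participant_id for n in nights}
        | set(records["participant_id"].astype(str))
        | {r.participant_id for r in responses}
    )
    bundles = []
    for pid in pids:
        gt = truth.get(pid, {"label": -1, "dropped_days": [], "days": {}})
        bundles.append(
            ParticipantBundle(
                participant_id=pid,
                true_label=int(gt.get("label", -1)),
                ppg_segments=[s for s in segments if s.participant_id == pid],
                ibi_windows=[w for w in ibi_windows if w.participant_id == pid],
                sleep_nights=[n for n in nights if n.participant_id == pid],
                activity_records=records.loc[
                    records["participant_id"].astype(str) == pid
                ].reset_index(drop=True),
                ucla_responses=[r for r in responses if r.participant_id == pid],
                ground_truth=gt,
            )
        )
    return bundles


def write_daily_features(daily_by_pid: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for pid, df in daily_by_pid.items():
        out = df.copy()
        out.insert(0, "date", [str(d.date()) for d in out.index])
        out.insert(0, "participant_id", pid)
        frames.append(out.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
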