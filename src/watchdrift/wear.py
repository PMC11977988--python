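"""Wear-time estimation from heart-rate sampling gaps.

The watch only records heart rate while worn, so long intervals without a
measurement indicate the device is off-wrist.  Any inter-measurement
interval of ``gap_threshold_minutes`` (default 40, inclusive) or longer is a
non-wear segment.  The first and last day of a participant's record range
use the range boundaries (midnight) as virtual measurements, so a late
first measurement creates a leading gap.  Segments spanning midnight are
split at midnight and each part attributed to its own date, which preserves
the per-day conservation invariant ``wear + nonwear = 1440``.

A calendar day is a *valid wear day* when estimated wear is at least 600
minutes ("under 600" is excluded, so exactly 600 is retained).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440.0
DEFAULT_GAP_THRESHOLD = 40.0
VALID_WEAR_MINUTES = 600.0

SEGMENT_COLUMNS = ["participant_id", "start", "end", "duration_minutes"]
WEAR_COLUMNS = ["participant_id", "date", "nonwear_minutes", "wear_minutes", "valid_day"]


def participant_date_ranges(
    heart_rate: pd.DataFrame, activity: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """First to last calendar date with any heart-rate or activity data.

    Returns columns ``participant_id, range_start, range_end`` (both
    normalized dates, inclusive).
    """
    parts = []
    if len(heart_rate):
        hr_dates = heart_rate["timestamp"].dt.normalize()
        parts.append(
            pd.DataFrame(
                {"participant_id": heart_rate["participant_id"], "date": hr_dates}
            )
        )
    if activity is not None and len(activity):
        parts.append(activity[["participant_id", "date"]])
    if not parts:
        return pd.DataFrame(columns=["participant_id", "range_start", "range_end"])
    alld = pd.concat(parts, ignore_index=True)
    g = alld.groupby("participant_id")["date"]
    out = pd.DataFrame({"range_start": g.min(), "range_end": g.max()}).reset_index()
    return out


def detect_nonwear_segments(
    heart_rate: pd.DataFrame,
    ranges: Optional[pd.DataFrame] = None,
    gap_threshold_minutes: float = DEFAULT_GAP_THRESHOLD,
) -> pd.DataFrame:
    """Find all non-wear segments (gaps >= threshold) per participant.

    ``ranges`` gives the analysis date range per participant (as from
    :func:`participant_date_ranges`); if omitted it is derived from the
    heart-rate data alone.  Records must be sorted by timestamp within
    participant; unsorted input is a hard error.

    Returns columns ``participant_id, start, end, duration_minutes``.
    A participant-date covered by the range but without any measurement
    falls entirely inside one segment.
    """
    if ranges is None:
        ranges = participant_date_ranges(heart_rate)
    thr = float(gap_threshold_minutes)
    rows_pid = []
    rows_start = []
    rows_end = []
    hr_by_pid = dict(iter(heart_rate.groupby("participant_id", sort=False))) if len(heart_rate) else {}
    for _, rng in ranges.iterrows():
        pid = rng["participant_id"]
        start = rng["range_start"]
        end_excl = rng["range_end"] + pd.Timedelta(days=1)
        sub = hr_by_pid.get(pid)
        if sub is not None:
            ts = sub["timestamp"].to_numpy()
            if len(ts) > 1 and (np.diff(ts) < np.timedelta64(0, "ns")).any():
                raise ValueError(f"detect_nonwear_segments: unsorted timestamps for participant {pid!r}")
            t = (ts - start.to_numpy()) / np.timedelta64(1, "m")
        else:
            t = np.empty(0)
        total = (end_excl - start).total_seconds() / 60.0
        aug = np.concatenate(([0.0], t, [total]))
        gaps = np.diff(aug)
        idx = np.nonzero(gaps >= thr)[0]
        for i in idx:
            rows_pid.append(pid)
            rows_start.append(start + pd.Timedelta(minutes=aug[i]))
            rows_end.append(start + pd.Timedelta(minutes=aug[i + 1]))
    out = pd.DataFrame({"participant_id": rows_pid, "start": rows_start, "end": rows_end})
    if len(out):
        out["duration_minutes"] = (out["end"] - out["start"]).dt.total_seconds() / 60.0
    else:
        out = pd.DataFrame(columns=SEGMENT_COLUMNS)
    return out


def daily_wear_minutes(segments: pd.DataFrame, ranges: pd.DataFrame) -> pd.DataFrame:
    """Per-date non-wear/wear accounting over each participant's range.

    Segments spanning midnight are split at midnight; per date,
    ``nonwear_minutes`` sums the overlapping segment parts,
    ``wear_minutes = 1440 - nonwear_minutes`` and
    ``valid_day = wear_minutes >= 600``.
    """
    seg_by_pid = (
        dict(iter(segments.groupby("participant_id", sort=False))) if len(segments) else {}
    )
    frames = []
    for _, rng in ranges.iterrows():
        pid = rng["participant_id"]
        start = rng["range_start"]
        n_days = int((rng["range_end"] - start).days) + 1
        bounds = np.arange(n_days + 1) * MINUTES_PER_DAY
        sub = seg_by_pid.get(pid)
        if sub is not None and len(sub):
            s = ((sub["start"] - start).dt.total_seconds() / 60.0).to_numpy()
            e = ((sub["end"] - start).dt.total_seconds() / 60.0).to_numpy()
            order = np.argsort(s)
            s, e = s[order], e[order]
            seg_len = e - s
            cum_prev = np.concatenate(([0.0], np.cumsum(seg_len)))[:-1]

            def coverage(x: np.ndarray) -> np.ndarray:
                i = np.searchsorted(s, x, side="right") - 1
                safe = np.maximum(i, 0)
                base = np.where(i >= 0, cum_prev[safe], 0.0)
                part = np.where(i >= 0, np.clip(x - s[safe], 0.0, seg_len[safe]), 0.0)
                return base + part

            cov = coverage(bounds)
            nonwear = np.diff(cov)
        else:
            nonwear = np.zeros(n_days)
        nonwear = np.clip(nonwear, 0.0, MINUTES_PER_DAY)
        wear = MINUTES_PER_DAY - nonwear
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "date": start + pd.to_timedelta(np.arange(n_days), unit="D"),
                    "nonwear_minutes": nonwear,
                    "wear_minutes": wear,
                    "valid_day": wear >= VALID_WEAR_MINUTES,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WEAR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def compute_daily_wear(
    heart_rate: pd.DataFrame,
    activity: Optional[pd.DataFrame] = None,
    gap_threshold_minutes: float = DEFAULT_GAP_THRESHOLD,
) -> pd.DataFrame:
    """Convenience: ranges -> segments -> daily wear table in one call."""
    ranges = participant_date_ranges(heart_rate, activity)
    segments = detect_nonwear_segments(heart_rate, ranges, gap_threshold_minutes)
    return daily_wear_minutes(segments, ranges)
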