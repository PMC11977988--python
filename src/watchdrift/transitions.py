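"""Transition detection, eligibility rules, and 14-day analysis windows.

A *transition date* is the first day on which a strict majority (> 1/2) of
the participant's heart-rate measurements carry the new software or
hardware version.  Each detected transition is screened:

* software events are ineligible unless they move between consecutive
  major versions (5->6, 6->7, 7->8, 8->9), and are excluded when the major
  software version changes more than once in the 14-day window, when the
  hardware version changes at any point in the window, or when a week has
  no (filtered) activity data;
* hardware events are excluded when the software version changes anywhere
  in the window, when there is more than the single hardware change in the
  window (the pre-week must be entirely on the old device and the
  post-week entirely on the new one), or when a week has no activity data.

Exclusion reasons accumulate rather than short-circuit, so an event can
carry several.

The *treatment* window spans day offsets -7..+6 around the transition date
(the transition date opens the post week); the *control* window spans the
two fully pre-upgrade weeks at offsets -14..-8 and -7..-1.  Both windows
are 14 days, so treatment and control overlap exactly on offsets -7..-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

SOFTWARE = "software"
HARDWARE = "hardware"

CONSECUTIVE_SOFTWARE = {(5, 6), (6, 7), (7, 8), (8, 9)}

REASON_NON_CONSECUTIVE = "non_consecutive"
REASON_MULTIPLE_SOFTWARE = "multiple_software_changes"
REASON_HARDWARE_IN_WINDOW = "hardware_change_in_window"
REASON_SOFTWARE_IN_WINDOW = "software_change_in_window"
REASON_MULTIPLE_HARDWARE = "multiple_hardware_changes"
REASON_MISSING_WEEK = "missing_week"

ALL_REASONS = (
    REASON_NON_CONSECUTIVE,
    REASON_MULTIPLE_SOFTWARE,
    REASON_HARDWARE_IN_WINDOW,
    REASON_SOFTWARE_IN_WINDOW,
    REASON_MULTIPLE_HARDWARE,
    REASON_MISSING_WEEK,
)

PANEL_COLUMNS = [
    "transition",
    "window_type",
    "participant_id",
    "transition_date",
    "date",
    "day_offset",
    "post",
    "weekday",
    "exercise_minutes",
    "active_calories",
    "sex",
]


@dataclass(frozen=True)
class TransitionEvent:
    """One detected per-participant version change with its verdict."""

    participant_id: str
    kind: str  # 'software' or 'hardware'
    from_version: str
    to_version: str
    transition_date: pd.Timestamp
    eligible: Optional[bool] = None
    exclusion_reasons: FrozenSet[str] = field(default_factory=frozenset)

    @property
    def label(self) -> str:
        if self.kind == SOFTWARE:
            return f"watchOS {self.from_version} to {self.to_version}"
        return "hardware"

    def window(self) -> pd.DatetimeIndex:
        return pd.date_range(self.transition_date - pd.Timedelta(days=7), periods=14)


def events_to_frame(events: Iterable[TransitionEvent]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": e.participant_id,
            "kind": e.kind,
            "from_version": e.from_version,
            "to_version": e.to_version,
            "transition_date": e.transition_date,
            "eligible": e.eligible,
            "exclusion_reasons": "|".join(sorted(e.exclusion_reasons)),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "kind",
            "from_version",
            "to_version",
            "transition_date",
            "eligible",
            "exclusion_reasons",
        ],
    )


def _kind_series(day_versions: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Observed (participant, date, version) days for one exposure kind."""
    if kind == SOFTWARE:
        sub = day_versions.dropna(subset=["major_software"])
        version = sub["major_software"].astype(int).astype(str)
    elif kind == HARDWARE:
        sub = day_versions.dropna(subset=["hardware_name"])
        sub = sub[sub["hardware_name"] != "unknown"]
        version = sub["hardware_name"].astype(str)
    else:
        raise ValueError(f"unknown transition kind {kind!r}")
    return pd.DataFrame(
        {"participant_id": sub["participant_id"], "date": sub["date"], "version": version}
    ).sort_values(["participant_id", "date"], kind="mergesort")


def detect_transitions(
    day_versions: pd.DataFrame, counts: pd.DataFrame, kind: str
) -> List[TransitionEvent]:
    """Detect version changes and their strict-majority transition dates.

    ``day_versions`` is the winner table from
    :func:`watchdrift.versions.assign_day_versions`;  ``counts`` the long
    count table from :func:`watchdrift.versions.day_version_counts` (used
    to evaluate the strict-majority rule day by day: a day on which the new
    version has exactly half of the measurements does not qualify).
    """
    series = _kind_series(day_versions, kind)
    kc = counts[counts["kind"] == kind]
    if kind == HARDWARE:
        kc = kc[kc["version"] != "unknown"]
    totals = kc.groupby(["participant_id", "date"])["n"].sum()
    n_lookup = kc.set_index(["participant_id", "date", "version"])["n"]

    events: List[TransitionEvent] = []
    for pid, sub in series.groupby("participant_id", sort=True):
        dates = sub["date"].to_numpy()
        versions = sub["version"].to_numpy()
        for i in range(1, len(versions)):
            if versions[i] == versions[i - 1]:
                continue
            old, new = versions[i - 1], versions[i]
            tdate = None
            # scan forward from the mode-change day for the first strict majority
            for j in range(i, len(versions)):
                if versions[j] != new and j > i:
                    break  # a different move began before new ever won a majority
                d = pd.Timestamp(dates[j])
                tot = totals.get((pid, d), 0)
                n_new = n_lookup.get((pid, d, new), 0)
                if tot > 0 and n_new * 2 > tot:
                    tdate = d
                    break
            if tdate is not None:
                events.append(TransitionEvent(pid, kind, old, new, tdate))
    return events


def _change_days(series: pd.DataFrame) -> pd.DataFrame:
    """Days on which the day-version differs from the previous observed day."""
    s = series.sort_values(["participant_id", "date"], kind="mergesort")
    prev = s.groupby("participant_id")["version"].shift()
    changed = prev.notna() & (s["version"] != prev)
    return s.loc[changed, ["participant_id", "date"]]


class _EligibilityContext:
    """Per-participant lookups shared across many eligibility checks."""

    def __init__(self, day_versions: pd.DataFrame, activity: pd.DataFrame):
        sw_series = _kind_series(day_versions, SOFTWARE)
        hw_series = _kind_series(day_versions, HARDWARE)
        self.sw_changes = {
            pid: set(sub["date"])
            for pid, sub in _change_days(sw_series).groupby("participant_id", sort=False)
        }
        self.hw_changes = {
            pid: set(sub["date"])
            for pid, sub in _change_days(hw_series).groupby("participant_id", sort=False)
        }
        self.hw_days = {
            pid: dict(zip(sub["date"], sub["version"]))
            for pid, sub in hw_series.groupby("participant_id", sort=False)
        }
        self.activity_days = {
            pid: set(sub["date"])
            for pid, sub in activity.groupby("participant_id", sort=False)
        }


def assess_eligibility(
    event: TransitionEvent,
    day_versions: pd.DataFrame,
    activity: pd.DataFrame,
    _ctx: Optional[_EligibilityContext] = None,
) -> TransitionEvent:
    """Apply the exclusion rules to one event.

    ``activity`` must already be person-day filtered (invalid wear days and
    outlier days removed), so a week whose days were all invalid counts as
    having no activity data.
    """
    ctx = _ctx if _ctx is not None else _EligibilityContext(day_versions, activity)
    pid = event.participant_id
    t = event.transition_date
    pre = set(pd.date_range(t - pd.Timedelta(days=7), periods=7))
    post = set(pd.date_range(t, periods=7))
    wset = pre | post

    sw_in_w = ctx.sw_changes.get(pid, set()) & wset
    hw_in_w = ctx.hw_changes.get(pid, set()) & wset

    reasons = set()
    if event.kind == SOFTWARE:
        pair = (int(event.from_version), int(event.to_version))
        if pair not in CONSECUTIVE_SOFTWARE:
            reasons.add(REASON_NON_CONSECUTIVE)
        if len(sw_in_w) > 1:
            reasons.add(REASON_MULTIPLE_SOFTWARE)
        if hw_in_w:
            reasons.add(REASON_HARDWARE_IN_WINDOW)
    else:
        if sw_in_w:
            reasons.add(REASON_SOFTWARE_IN_WINDOW)
        hw_days = ctx.hw_days.get(pid, {})
        pre_versions = {v for d, v in hw_days.items() if d in pre}
        post_versions = {v for d, v in hw_days.items() if d in post}
        impure = bool(pre_versions - {event.from_version}) or bool(
            post_versions - {event.to_version}
        )
        if len(hw_in_w) > 1 or impure:
            reasons.add(REASON_MULTIPLE_HARDWARE)

    adays = ctx.activity_days.get(pid, set())
    if not (adays & pre) or not (adays & post):
        reasons.add(REASON_MISSING_WEEK)

    return replace(event, eligible=not reasons, exclusion_reasons=frozenset(reasons))


def assess_all(
    events: Sequence[TransitionEvent],
    day_versions: pd.DataFrame,
    activity: pd.DataFrame,
) -> List[TransitionEvent]:
    ctx = _EligibilityContext(day_versions, activity)
    return [assess_eligibility(e, day_versions, activity, _ctx=ctx) for e in events]


def build_panels(
    events: Sequence[TransitionEvent],
    activity: pd.DataFrame,
    participants: pd.DataFrame,
    completeness_days: int = 7,
    window_type: str = "treatment",
) -> pd.DataFrame:
    """Assemble the person-day analysis table for the eligible events.

    ``activity`` must be the filtered person-day table.  A
    participant-transition contributes only when each half-window has at
    least ``completeness_days`` activity days (7 = the primary
    all-14-days restriction; 1, 4, 5 and 6 are the sensitivity settings).
    For the treatment window, offsets -7..-1 are pre (post=0) and 0..+6
    post (post=1); for the control window, offsets -14..-8 are pre and
    -7..-1 post.  When one participant has several eligible events with
    the same label, only the earliest is used, so each model sees at most
    one window per participant.
    """
    if window_type not in ("treatment", "control"):
        raise ValueError(f"unknown window_type {window_type!r}")
    if completeness_days not in (1, 2, 3, 4, 5, 6, 7):
        raise ValueError("completeness_days must be in 1..7")
    eligible = [e for e in events if e.eligible]
    # at most one window per participant per transition label (earliest)
    chosen = {}
    for e in sorted(eligible, key=lambda e: (e.label, e.participant_id, e.transition_date)):
        chosen.setdefault((e.label, e.participant_id), e)
    sex_map = dict(zip(participants["participant_id"], participants["sex"]))
    act = activity.set_index(["participant_id", "date"])

    frames = []
    for e in chosen.values():
        t = e.transition_date
        if window_type == "treatment":
            offsets = np.arange(-7, 7)
            post_flag = (offsets >= 0).astype(int)
        else:
            offsets = np.arange(-14, 0)
            post_flag = (offsets >= -7).astype(int)
        dates = t + pd.to_timedelta(offsets, unit="D")
        rows = []
        for off, p, d in zip(offsets, post_flag, dates):
            key = (e.participant_id, d)
            if key in act.index:
                rec = act.loc[key]
                rows.append(
                    {
                        "transition": e.label,
                        "window_type": window_type,
                        "participant_id": e.participant_id,
                        "transition_date": t,
                        "date": d,
                        "day_offset": int(off),
                        "post": int(p),
                        "weekday": d.day_name(),
                        "exercise_minutes": float(rec["exercise_minutes"]),
                        "active_calories": float(rec["active_calories"]),
                        "sex": sex_map.get(e.participant_id),
                    }
                )
        sub = pd.DataFrame(rows)
        if len(sub):
            n_pre = int((sub["post"] == 0).sum())
            n_post = int((sub["post"] == 1).sum())
            if n_pre >= completeness_days and n_post >= completeness_days:
                frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["transition", "participant_id", "date"], kind="mergesort")
        .reset_index(drop=True)[PANEL_COLUMNS]
    )
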