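import numpy as np
import pandas as pd
import pytest

import watchdrift as wd
from watchdrift import transitions
from watchdrift.transitions import (
    REASON_HARDWARE_IN_WINDOW,
    REASON_MISSING_WEEK,
    REASON_MULTIPLE_HARDWARE,
    REASON_NON_CONSECUTIVE,
    build_panels,
)

START = pd.Timestamp("2021-09-01")


def _hr_from_daily_mix(mix, pid="p", old="7.1", new="8.0", product="Watch6,2"):
    """One row per measurement; ``mix`` lists (n_old, n_new) per consecutive day."""
    rows = []
    for d, (n_old, n_new) in enumerate(mix):
        day = START + pd.Timedelta(days=d)
        for k in range(n_old + n_new):
            rows.append(
                (
                    pid,
                    day + pd.Timedelta(minutes=5 * k),
                    70.0,
                    old if k < n_old else new,
                    product,
                )
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "timestamp", "bpm", "source_version", "product_type"]
    )


def _detect(hr, kind="software"):
    counts = wd.day_version_counts(hr)
    dv = wd.assign_day_versions(hr)
    return wd.detect_transitions(dv, counts, kind), dv


def _activity(pid, start, n_days, exercise=40.0, calories=600.0):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "date": start + pd.to_timedelta(np.arange(n_days), unit="D"),
            "exercise_minutes": exercise,
            "active_calories": calories,
        }
    )


class TestDetectTransitions:
    def test_first_strict_majority_day(self):
        # new-version shares by day: 0.2, 0.4, 0.6, 1.0 -> transition on day 3
        events, _ = _detect(_hr_from_daily_mix([(8, 2), (6, 4), (4, 6), (0, 10)]))
        assert len(events) == 1
        assert events[0].transition_date == START + pd.Timedelta(days=2)
        assert (events[0].from_version, events[0].to_version) == ("7", "8")

    def test_exact_half_does_not_qualify(self):
        # share exactly 0.5 then 0.9 -> transition on the 0.9 day
        events, _ = _detect(_hr_from_daily_mix([(10, 0), (5, 5), (1, 9)]))
        assert len(events) == 1
        assert events[0].transition_date == START + pd.Timedelta(days=2)

    def test_two_separate_changes_two_events(self):
        mix = [(10, 0)] * 14 + [(0, 10)] * 14
        hr1 = _hr_from_daily_mix(mix, old="5.3", new="6.1")
        hr2 = _hr_from_daily_mix([(0, 10)] * 14, old="6.1", new="7.0")
        hr2["timestamp"] += pd.Timedelta(days=28)
        events, _ = _detect(pd.concat([hr1, hr2], ignore_index=True))
        assert [(e.from_version, e.to_version) for e in events] == [("5", "6"), ("6", "7")]


class TestEligibility:
    def test_non_consecutive_jump(self):
        hr = _hr_from_daily_mix([(10, 0)] * 10 + [(0, 10)] * 10, old="5.3", new="7.0")
        events, dv = _detect(hr)
        activity = _activity("p", START, 20)
        e = transitions.assess_eligibility(events[0], dv, activity)
        assert e.exclusion_reasons == frozenset({REASON_NON_CONSECUTIVE})

    def test_hardware_swap_in_window(self):
        hr = _hr_from_daily_mix([(10, 0)] * 10 + [(0, 10)] * 10)
        swap_day = START + pd.Timedelta(days=13)  # transition day +3
        hr.loc[hr["timestamp"] >= swap_day, "product_type"] = "Watch6,7"
        events, dv = _detect(hr)
        sw = [e for e in events if e.kind == "software"][0]
        e = transitions.assess_eligibility(sw, dv, _activity("p", START, 20))
        assert REASON_HARDWARE_IN_WINDOW in e.exclusion_reasons

    def test_alternating_hardware_multiple_changes(self):
        hr = _hr_from_daily_mix([(10, 0)] * 21, old="7.1", new="7.1")
        day = (hr["timestamp"] - START).dt.days
        hr["product_type"] = np.select(
            [day < 7, day < 10, day < 13], ["Watch6,1", "Watch6,7", "Watch6,1"], "Watch6,7"
        )
        events, dv = _detect(hr, "hardware")
        assessed = [
            transitions.assess_eligibility(e, dv, _activity("p", START, 21)) for e in events
        ]
        assert len(assessed) == 3
        assert all(REASON_MULTIPLE_HARDWARE in e.exclusion_reasons for e in assessed)

    def test_missing_week(self):
        hr = _hr_from_daily_mix([(10, 0)] * 10 + [(0, 10)] * 10)
        events, dv = _detect(hr)
        post_only = _activity("p", START + pd.Timedelta(days=10), 10)
        e = transitions.assess_eligibility(events[0], dv, post_only)
        assert REASON_MISSING_WEEK in e.exclusion_reasons


class TestBuildPanels:
    @pytest.fixture
    def eligible_event(self):
        hr = _hr_from_daily_mix([(10, 0)] * 16 + [(0, 10)] * 12)
        events, dv = _detect(hr)
        return events[0], dv

    def _participants(self):
        return pd.DataFrame({"participant_id": ["p"], "sex": ["female"]})

    def test_complete_window_14_rows(self, eligible_event):
        event, dv = eligible_event
        activity = _activity("p", START, 28)
        e = transitions.assess_eligibility(event, dv, activity)
        panel = build_panels([e], activity, self._participants(), 7, "treatment")
        assert len(panel) == 14
        assert list(panel["day_offset"]) == list(range(-7, 7))
        assert (panel.loc[panel["day_offset"] >= 0, "post"] == 1).all()
        assert (panel.loc[panel["day_offset"] < 0, "post"] == 0).all()

    def test_completeness_threshold(self, eligible_event):
        event, dv = eligible_event
        activity = _activity("p", START, 28)
        gap = event.transition_date + pd.Timedelta(days=2)
        activity = activity[activity["date"] != gap]
        e = transitions.assess_eligibility(event, dv, activity)
        assert len(build_panels([e], activity, self._participants(), 7, "treatment")) == 0
        assert len(build_panels([e], activity, self._participants(), 6, "treatment")) == 13

    def test_control_window_precedes_upgrade(self, eligible_event):
        event, dv = eligible_event
        activity = _activity("p", START, 28)
        e = transitions.assess_eligibility(event, dv, activity)
        panel = build_panels([e], activity, self._participants(), 7, "control")
        assert len(panel) == 14
        assert (panel["date"] < e.transition_date).all()
        assert (panel.loc[panel["day_offset"] >= -7, "post"] == 1).all()

    def test_treatment_control_overlap_geometry(self, eligible_event):
        event, dv = eligible_event
        activity = _activity("p", START, 28)
        e = transitions.assess_eligibility(event, dv, activity)
        t = build_panels([e], activity, self._participants(), 7, "treatment")
        c = build_panels([e], activity, self._participants(), 7, "control")
        overlap = set(t["date"]) & set(c["date"])
        assert overlap == set(e.transition_date + pd.to_timedelta(range(-7, 0), unit="D"))

    def test_raising_completeness_never_adds_participants(self, small_cohort):
        res = wd.run_full_analysis(
            small_cohort.heart_rate,
            small_cohort.activity,
            small_cohort.participants,
            fit_models=False,
            sensitivity=False,
        )
        prev = None
        for c in (1, 4, 7):
            panels = transitions.build_panels(
                res["events"], res["activity_filtered"], small_cohort.participants, c, "treatment"
            )
            n = panels.groupby("transition")["participant_id"].nunique() if len(panels) else {}
            if prev is not None:
                for label in set(prev.keys()) | set(dict(n).keys()):
                    assert dict(n).get(label, 0) <= prev.get(label, np.inf)
            prev = dict(n)

    def test_panel_versions_match_event(self, small_cohort):
        """Pre-week days run the old version, post-week days the new one."""
        res = wd.run_full_analysis(
            small_cohort.heart_rate,
            small_cohort.activity,
            small_cohort.participants,
            fit_models=False,
            sensitivity=False,
        )
        events = [e for e in res["events"] if e.eligible and e.kind == "software"]
        dv = res["day_versions"].set_index(["participant_id", "date"])["major_software"]
        for e in events[:20]:
            for off in range(-7, 7):
                d = e.transition_date + pd.Timedelta(days=off)
                v = dv.get((e.participant_id, d))
                if pd.isna(v):
                    continue
                expected = int(e.to_version) if off >= 0 else int(e.from_version)
                assert v == expected, (e.participant_id, d, v, expected)
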