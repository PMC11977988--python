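import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import watchdrift as wd
from watchdrift.wear import (
    daily_wear_minutes,
    detect_nonwear_segments,
    participant_date_ranges,
)

DAY = pd.Timestamp("2021-05-03")


def _hr(minutes, pid="p", day=DAY):
    ts = day + pd.to_timedelta(np.asarray(minutes, dtype=float), unit="m")
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp": ts,
            "bpm": 70.0,
            "source_version": "7.1",
            "product_type": "Watch6,2",
        }
    )


def minute_grid_oracle(minutes, total_minutes, threshold):
    """Brute force: a minute is non-wear iff it lies in an interval >= threshold
    between consecutive measurements (range boundaries count as measurements)."""
    pts = np.concatenate(([0.0], np.sort(np.asarray(minutes, float)), [total_minutes]))
    nonwear = np.zeros(int(total_minutes), dtype=bool)
    for a, b in zip(pts[:-1], pts[1:]):
        if b - a >= threshold:
            nonwear[int(a): int(b)] = True
    # per-day sums
    return [
        float(nonwear[d * 1440: (d + 1) * 1440].sum())
        for d in range(int(total_minutes) // 1440)
    ]


class TestSegments:
    def test_dense_day_no_segments(self):
        hr = _hr(np.arange(0, 1440, 5))
        segs = detect_nonwear_segments(hr)
        assert len(segs) == 0

    def test_threshold_inclusive_at_40(self):
        # dense except one exactly-40-minute gap: threshold is inclusive
        minutes = np.concatenate([np.arange(0, 601, 5), np.arange(640, 1440, 5)])
        segs = detect_nonwear_segments(_hr(minutes))
        assert len(segs) == 1
        assert segs["duration_minutes"].iloc[0] == pytest.approx(40.0)

    def test_below_threshold_no_segment(self):
        minutes = np.concatenate([np.arange(0, 601, 5), [639.9], np.arange(640, 1440, 5)])
        segs = detect_nonwear_segments(_hr(minutes))
        assert len(segs) == 0

    def test_uncovered_date_inside_one_segment(self):
        # day 1 and day 3 measured, day 2 empty: one long gap swallows day 2
        hr = pd.concat(
            [_hr(np.arange(0, 1440, 5)), _hr(np.arange(0, 1440, 5), day=DAY + pd.Timedelta(days=2))]
        ).sort_values("timestamp").reset_index(drop=True)
        segs = detect_nonwear_segments(hr)
        assert len(segs) == 1
        covered = (segs["start"].iloc[0] <= DAY + pd.Timedelta(days=1)) and (
            segs["end"].iloc[0] >= DAY + pd.Timedelta(days=2)
        )
        assert covered
        wear = daily_wear_minutes(segs, participant_date_ranges(hr))
        mid = wear[wear["date"] == DAY + pd.Timedelta(days=1)]
        assert mid["nonwear_minutes"].iloc[0] == 1440.0
        assert not mid["valid_day"].iloc[0]

    def test_unsorted_raises(self):
        hr = _hr([100, 50, 200])
        with pytest.raises(ValueError, match="unsorted"):
            detect_nonwear_segments(hr)

    def test_late_first_measurement_leading_gap(self):
        hr = _hr(np.arange(300, 1440, 5))  # first measurement at 05:00
        segs = detect_nonwear_segments(hr)
        assert len(segs) == 1
        assert segs["start"].iloc[0] == DAY
        assert segs["duration_minutes"].iloc[0] == pytest.approx(300.0)


class TestDailyWear:
    def test_midnight_split(self):
        # continuous 5-min sampling except a gap 23:30 (day 1) -> 01:30 (day 2)
        m1 = np.arange(0, 1411, 5)  # to 23:30
        m2 = np.arange(1530, 2880, 5)  # from 01:30 next day
        hr = _hr(np.concatenate([m1, m2]))
        wear = wd.compute_daily_wear(hr)
        assert list(wear["nonwear_minutes"]) == [30.0, 90.0]
        assert list(wear["wear_minutes"]) == [1410.0, 1350.0]

    def test_exactly_600_wear_is_valid(self, toy, toy_pipeline):
        row = toy_pipeline["wear"].query(
            "participant_id == 'anna' and date == @pd.Timestamp('2021-09-06')"
        ).iloc[0]
        assert row["wear_minutes"] == 600.0
        assert bool(row["valid_day"])

    def test_conservation(self, toy_pipeline):
        w = toy_pipeline["wear"]
        np.testing.assert_allclose(w["wear_minutes"] + w["nonwear_minutes"], 1440.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    minutes=st.lists(st.integers(min_value=0, max_value=3 * 1440 - 1), min_size=1, max_size=200),
    threshold=st.sampled_from([20.0, 40.0, 90.0]),
)
def test_segment_algorithm_matches_minute_grid_oracle(minutes, threshold):
    """On minute-aligned timestamps the interval algorithm and a brute-force
    per-minute simulation agree exactly on daily non-wear totals."""
    minutes = sorted(set(minutes))
    hr = _hr(minutes)
    ranges = pd.DataFrame(
        {
            "participant_id": ["p"],
            "range_start": [DAY],
            "range_end": [DAY + pd.Timedelta(days=2)],
        }
    )
    segs = detect_nonwear_segments(hr, ranges, threshold)
    wear = daily_wear_minutes(segs, ranges)
    expected = minute_grid_oracle(minutes, 3 * 1440, threshold)
    np.testing.assert_allclose(wear["nonwear_minutes"].to_numpy(), expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    minutes=st.lists(st.integers(min_value=0, max_value=1439), min_size=1, max_size=80),
)
def test_lower_threshold_never_decreases_nonwear(minutes):
    minutes = sorted(set(minutes))
    hr = _hr(minutes)
    totals = []
    for thr in (120.0, 40.0, 10.0):
        wear = wd.compute_daily_wear(hr, gap_threshold_minutes=thr)
        totals.append(wear["nonwear_minutes"].sum())
    assert totals[0] <= totals[1] <= totals[2]
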