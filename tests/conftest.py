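import numpy as np
import pandas as pd
import pytest

import watchdrift as wd
from watchdrift import filters, transitions


@pytest.fixture(scope="session")
def toy():
    return wd.generate_worked_toy()


@pytest.fixture(scope="session")
def toy_pipeline(toy):
    """Shared intermediate tables for the worked toy fixture."""
    index = wd.load_hardware_index()
    wear = wd.compute_daily_wear(toy.heart_rate, toy.activity)
    thresholds = filters.percentile_thresholds(toy.activity, toy.participants)
    activity_filtered, exclusions = filters.apply_exclusions(
        toy.activity, wear, thresholds, toy.participants
    )
    counts = wd.day_version_counts(toy.heart_rate, index)
    day_versions = wd.assign_day_versions(toy.heart_rate, index)
    events = wd.detect_transitions(day_versions, counts, "software") + wd.detect_transitions(
        day_versions, counts, "hardware"
    )
    assessed = transitions.assess_all(events, day_versions, activity_filtered)
    return {
        "wear": wear,
        "thresholds": thresholds,
        "activity_filtered": activity_filtered,
        "exclusions": exclusions,
        "counts": counts,
        "day_versions": day_versions,
        "events": assessed,
    }


@pytest.fixture(scope="session")
def small_cohort():
    return wd.generate_cohort(wd.GeneratorConfig(n_participants=30, seed=11))


def make_heart_rate(pid, timestamps, version="7.3.1", product="Watch6,2", bpm=72.0):
    """Minimal heart-rate frame for hand-built scenarios."""
    ts = pd.to_datetime(list(timestamps))
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp": ts,
            "bpm": bpm,
            "source_version": version,
            "product_type": product,
        }
    )


@pytest.fixture
def hr_builder():
    return make_heart_rate
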