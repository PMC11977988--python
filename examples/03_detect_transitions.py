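"""Assign day-level versions, detect transitions, and screen eligibility.

The day-level software exposure is the modal major version of the day's
heart-rate measurements (ties go to the newer version); the transition
date is the first day on which the *new* version has a strict majority.
Events are then screened: consecutive-version rule, no second software
change in the 14-day window, no hardware change in window (and the mirror
rules for hardware events), and activity data in both weeks.
"""

from watchdrift import (
    assign_day_versions,
    compute_daily_wear,
    day_version_counts,
    detect_transitions,
    events_to_frame,
    generate_worked_toy,
    load_hardware_index,
)
from watchdrift.filters import apply_exclusions, percentile_thresholds
from watchdrift.transitions import assess_all

toy = generate_worked_toy()
index = load_hardware_index()

wear = compute_daily_wear(toy.heart_rate, toy.activity)
thresholds = percentile_thresholds(toy.activity, toy.participants)
activity, _ = apply_exclusions(toy.activity, wear, thresholds, toy.participants)

counts = day_version_counts(toy.heart_rate, index)
day_versions = assign_day_versions(toy.heart_rate, index)
events = detect_transitions(day_versions, counts, "software") + detect_transitions(
    day_versions, counts, "hardware"
)
assessed = assess_all(events, day_versions, activity)

print(events_to_frame(assessed).to_string(index=False))
print(
    "\nOnly anna's watchOS 7->8 event survives screening. Note her transition "
    "date is 2021-09-20: on 09-19 exactly half of her measurements were on "
    "version 8, and 'most' means a strict majority."
)
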