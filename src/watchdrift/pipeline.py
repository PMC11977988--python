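"""End-to-end orchestration: raw tables in, result tables out.

``run_full_analysis`` chains every stage on in-memory tables;
``simulate_to_dir`` / ``analyze_dir`` are the file-based entry points used
by the example scripts (CSV dialects from :mod:`watchdrift.records`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import pandas as pd

from . import filters, records, transitions, versions, wear
from .descriptives import change_summary_grid
from .nbglmm import ModelSpec, fit_nb_glmm
from .simulate import Cohort, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

TRANSITION_LABELS = (
    "watchOS 5 to 6",
    "watchOS 6 to 7",
    "watchOS 7 to 8",
    "watchOS 8 to 9",
    "hardware",
)
WINDOW_TYPES = ("treatment", "control")
STRATA = ("overall", "female", "male")
SENSITIVITY_COMPLETENESS = (1, 4, 5, 6)


def _fit_cell(panel: pd.DataFrame, spec: ModelSpec) -> Optional[dict]:
    try:
        return fit_nb_glmm(panel, spec).to_row()
    except (ValueError, KeyError) as exc:
        logger.warning(
            "model cell skipped (%s, stratum=%s, adjusted=%s, outcome=%s): %s",
            panel["transition"].iloc[0] if len(panel) else "?",
            spec.stratum, spec.adjust_weekday, spec.outcome, exc,
        )
        return None


def _fit_all_models(panels: Dict[tuple, pd.DataFrame], n_quad: int) -> pd.DataFrame:
    rows = []
    for (label, window_type), panel in panels.items():
        if panel is None or not len(panel):
            logger.warning("empty panel for %s / %s", label, window_type)
            continue
        for outcome in records.OUTCOMES:
            for stratum in STRATA:
                for adjusted in (False, True):
                    spec = ModelSpec(
                        outcome=outcome,
                        adjust_weekday=adjusted,
                        stratum=stratum,
                        n_quad=n_quad,
                    )
                    row = _fit_cell(panel, spec)
                    if row is not None:
                        rows.append(row)
    return pd.DataFrame(rows)


def build_all_panels(
    events: Sequence[transitions.TransitionEvent],
    activity: pd.DataFrame,
    participants: pd.DataFrame,
    completeness_days: int = 7,
) -> Dict[tuple, pd.DataFrame]:
    """One panel per (transition label, window type)."""
    panels: Dict[tuple, pd.DataFrame] = {}
    for window_type in WINDOW_TYPES:
        full = transitions.build_panels(
            events, activity, participants, completeness_days, window_type
        )
        for label in TRANSITION_LABELS:
            sub = full[full["transition"] == label].reset_index(drop=True)
            panels[(label, window_type)] = sub
    return panels


def run_full_analysis(
    heart_rate: pd.DataFrame,
    activity: pd.DataFrame,
    participants: pd.DataFrame,
    completeness_days: int = 7,
    gap_threshold_minutes: float = 40.0,
    n_quad: int = 9,
    hardware_index: Optional[dict] = None,
    fit_models: bool = True,
    sensitivity: bool = True,
) -> dict:
    """Run the whole pipeline and return every intermediate and final table.

    Returns a dict with keys ``wear, thresholds, activity_filtered,
    exclusions, day_versions, counts, events, panels, results,
    change_summaries, sensitivity_changes, sensitivity_results`` (model
    tables empty when ``fit_models=False``; sensitivity tables empty when
    ``sensitivity=False``).  The primary analysis restricts to
    participant-windows with ``completeness_days`` (default 7 = all 14
    days) of activity data per half-window; sensitivity descriptives rerun
    at thresholds 1, 4, 5 and 6 and sensitivity models at threshold 1.
    """
    index = hardware_index if hardware_index is not None else versions.load_hardware_index()

    daily_wear = wear.compute_daily_wear(heart_rate, activity, gap_threshold_minutes)
    thresholds = filters.percentile_thresholds(activity, participants)
    activity_filtered, exclusions = filters.apply_exclusions(
        activity, daily_wear, thresholds, participants
    )

    counts = versions.day_version_counts(heart_rate, index)
    day_versions = versions.assign_day_versions(heart_rate, index)
    raw_events = transitions.detect_transitions(
        day_versions, counts, transitions.SOFTWARE
    ) + transitions.detect_transitions(day_versions, counts, transitions.HARDWARE)
    events = transitions.assess_all(raw_events, day_versions, activity_filtered)
    n_eligible = sum(bool(e.eligible) for e in events)
    logger.info(
        "run_full_analysis: %d transitions detected, %d eligible", len(events), n_eligible
    )

    panels = build_all_panels(events, activity_filtered, participants, completeness_days)
    change_summaries = change_summary_grid(list(panels.values()))
    results = _fit_all_models(panels, n_quad) if fit_models else pd.DataFrame()

    sensitivity_changes = pd.DataFrame()
    sensitivity_results = pd.DataFrame()
    if sensitivity:
        frames = []
        for c in SENSITIVITY_COMPLETENESS:
            p_c = build_all_panels(events, activity_filtered, participants, c)
            grid = change_summary_grid(list(p_c.values()))
            grid["completeness_days"] = c
            frames.append(grid)
            if c == 1 and fit_models:
                sensitivity_results = _fit_all_models(p_c, n_quad)
                sensitivity_results["completeness_days"] = c
        sensitivity_changes = pd.concat(frames, ignore_index=True)

    return {
        "wear": daily_wear,
        "thresholds": thresholds,
        "activity_filtered": activity_filtered,
        "exclusions": exclusions,
        "day_versions": day_versions,
        "counts": counts,
        "events": events,
        "panels": panels,
        "results": results,
        "change_summaries": change_summaries,
        "sensitivity_changes": sensitivity_changes,
        "sensitivity_results": sensitivity_results,
    }


def _coerce_config(config: Union[GeneratorConfig, dict, None]) -> GeneratorConfig:
    if config is None:
        return GeneratorConfig()
    if isinstance(config, GeneratorConfig):
        return config
    valid = {f.name for f in dataclasses.fields(GeneratorConfig)}
    for key in config:
        if key not in valid:
            raise ValueError(f"unknown generator config key {key!r}")
    return GeneratorConfig(**config)


def simulate_to_dir(
    config: Union[GeneratorConfig, dict, None], out_dir: Union[str, Path]
) -> Cohort:
    """Generate a cohort and write its four files to ``out_dir``.

    Writes ``heart_rate.csv, daily_activity.csv, participants.csv,
    ground_truth.json`` and logs summary counts.
    """
    cfg = _coerce_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    records.write_heart_rate_csv(cohort.heart_rate, out / "heart_rate.csv")
    records.write_daily_activity_csv(cohort.activity, out / "daily_activity.csv")
    records.write_participants_csv(cohort.participants, out / "participants.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1)
    logger.info(
        "simulate_to_dir: %d participants, %d heart-rate records, %d person-days, "
        "%d true upgrades -> %s",
        len(cohort.participants), len(cohort.heart_rate), len(cohort.activity),
        len(cohort.ground_truth["upgrades"]), out,
    )
    return cohort


def analyze_dir(
    in_dir: Union[str, Path],
    out_dir: Union[str, Path],
    completeness_days: int = 7,
    fit_models: bool = True,
    sensitivity: bool = False,
    n_quad: int = 9,
) -> dict:
    """Run the pipeline on a directory of input CSVs and write result files.

    Expects ``heart_rate.csv, daily_activity.csv, participants.csv`` in
    ``in_dir`` (a missing file is an error naming it); writes
    ``transitions.csv, exclusions.csv, daily_wear.csv, results.csv,
    change_summaries.csv`` to ``out_dir``.
    """
    ind = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("heart_rate.csv", "daily_activity.csv", "participants.csv"):
        if not (ind / name).exists():
            raise FileNotFoundError(f"analyze_dir: missing input file {ind / name}")
    heart_rate = records.read_heart_rate_csv(ind / "heart_rate.csv")
    activity = records.read_daily_activity_csv(ind / "daily_activity.csv")
    participants = records.read_participants_csv(ind / "participants.csv")

    res = run_full_analysis(
        heart_rate,
        activity,
        participants,
        completeness_days=completeness_days,
        n_quad=n_quad,
        fit_models=fit_models,
        sensitivity=sensitivity,
    )
    transitions.events_to_frame(res["events"]).to_csv(out / "transitions.csv", index=False)
    res["exclusions"].to_csv(out / "exclusions.csv", index=False)
    res["wear"].to_csv(out / "daily_wear.csv", index=False)
    if len(res["results"]):
        records.write_results_table(res["results"], out / "results.csv")
    res["change_summaries"].to_csv(out / "change_summaries.csv", index=False)
    return res
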