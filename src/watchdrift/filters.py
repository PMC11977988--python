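"""Person-day exclusions: sex-specific outlier days and invalid wear days.

Outlier thresholds are the 99.9th percentile of each outcome over *all*
recorded person-days of each sex (linear-interpolation quantile), computed
once on the pre-filter data.  A person-day is dropped when either outcome
lies strictly above its sex's threshold, when estimated wear time is under
600 minutes, or when the day has no wear record at all.  Each dropped day
is logged with its reasons (a day may carry several).
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd

from .records import OUTCOMES, SEXES

logger = logging.getLogger(__name__)

PERCENTILE = 0.999
MIN_RECOMMENDED_DAYS = 1000

REASON_LOW_WEAR = "low_wear"
REASON_NO_WEAR_RECORD = "no_wear_record"
REASON_OUTLIER = {
    "exercise_minutes": "outlier_exercise_minutes",
    "active_calories": "outlier_active_calories",
}


def percentile_thresholds(
    activity: pd.DataFrame,
    participants: pd.DataFrame,
    q: float = PERCENTILE,
) -> pd.DataFrame:
    """Per-sex 99.9th-percentile thresholds for each outcome.

    Returns a table ``sex, outcome, threshold`` using the
    linear-interpolation quantile definition.  A sex stratum with zero
    person-days is a hard error; strata below ~1000 person-days trigger a
    degeneracy warning (the quantile then sits between the two largest
    observations).
    """
    merged = activity.merge(participants, on="participant_id", how="left")
    if merged["sex"].isna().any():
        missing = merged.loc[merged["sex"].isna(), "participant_id"].unique()[:5]
        raise ValueError(f"percentile_thresholds: participants without sex, e.g. {list(missing)}")
    rows = []
    for sex in SEXES:
        sub = merged[merged["sex"] == sex]
        if not len(sub):
            raise ValueError(f"percentile_thresholds: no person-days for sex {sex!r}")
        if len(sub) < MIN_RECOMMENDED_DAYS:
            logger.warning(
                "percentile_thresholds: only %d person-days for sex %r; "
                "the %.1fth percentile is degenerate at this size",
                len(sub), sex, 100 * q,
            )
        for outcome in OUTCOMES:
            thr = float(np.quantile(sub[outcome].to_numpy(), q, method="linear"))
            rows.append({"sex": sex, "outcome": outcome, "threshold": thr})
            logger.info("percentile_thresholds: sex=%s %s -> %.4f", sex, outcome, thr)
    return pd.DataFrame(rows)


def apply_exclusions(
    activity: pd.DataFrame,
    wear: pd.DataFrame,
    thresholds: pd.DataFrame,
    participants: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded person-days; return (filtered activity, exclusion ledger).

    The ledger has one row per excluded person-day with a ``reasons``
    column joining all applicable reason codes with '|'.  Applying the
    filter again with the same thresholds removes nothing further.
    """
    merged = activity.merge(participants, on="participant_id", how="left").merge(
        wear[["participant_id", "date", "wear_minutes"]],
        on=["participant_id", "date"],
        how="left",
    )
    thr = thresholds.set_index(["sex", "outcome"])["threshold"]
    drop_mask = pd.Series(False, index=merged.index)
    reason_lists = [[] for _ in range(len(merged))]

    for outcome in OUTCOMES:
        lim = merged["sex"].map({s: thr.get((s, outcome), np.inf) for s in SEXES})
        over = merged[outcome] > lim
        drop_mask |= over
        for i in np.nonzero(over.to_numpy())[0]:
            reason_lists[i].append(REASON_OUTLIER[outcome])

    no_wear = merged["wear_minutes"].isna()
    low_wear = merged["wear_minutes"] < 600
    drop_mask |= no_wear | low_wear
    for i in np.nonzero(no_wear.to_numpy())[0]:
        reason_lists[i].append(REASON_NO_WEAR_RECORD)
    for i in np.nonzero(low_wear.fillna(False).to_numpy())[0]:
        reason_lists[i].append(REASON_LOW_WEAR)

    ledger = pd.DataFrame(
        {
            "participant_id": merged.loc[drop_mask, "participant_id"],
            "date": merged.loc[drop_mask, "date"],
            "reasons": ["|".join(reason_lists[i]) for i in np.nonzero(drop_mask.to_numpy())[0]],
        }
    ).reset_index(drop=True)
    kept = merged.loc[~drop_mask, list(activity.columns)].reset_index(drop=True)
    logger.info(
        "apply_exclusions: dropped %d of %d person-days (%d low wear, %d no wear record, "
        "%d exercise outliers, %d calorie outliers)",
        len(ledger), len(merged), int(low_wear.fillna(False).sum()), int(no_wear.sum()),
        int((merged["exercise_minutes"] > merged["sex"].map(
            {s: thr.get((s, "exercise_minutes"), np.inf) for s in SEXES})).sum()),
        int((merged["active_calories"] > merged["sex"].map(
            {s: thr.get((s, "active_calories"), np.inf) for s in SEXES})).sum()),
    )
    return kept, ledger
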