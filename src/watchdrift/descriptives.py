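"""Descriptive pre/post change summaries.

For each participant in a panel, the person-level change is the difference
between their post-week mean and pre-week mean daily outcome; the summary
reports the mean and sample SD of these changes (in outcome units) with
the number of contributing participants, overall and stratified by sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

STRATA = ("overall", "female", "male")


@dataclass(frozen=True)
class ChangeSummary:
    transition: str
    window_type: str
    stratum: str
    outcome: str
    mean_change: float
    sd_change: float  # NaN when n == 1
    n: int

    def to_row(self) -> dict:
        return dict(self.__dict__)


def person_level_change(
    panel: pd.DataFrame, outcome: str, stratum: str = "overall"
) -> Optional[ChangeSummary]:
    """Mean +- SD of per-participant (post-week mean - pre-week mean).

    Participants contribute only if they have at least one day in each
    half-window.  Returns None (and is logged by callers) for an empty
    stratum.
    """
    sub = panel if stratum == "overall" else panel[panel["sex"] == stratum]
    if not len(sub):
        return None
    means = sub.pivot_table(
        index="participant_id", columns="post", values=outcome, aggfunc="mean"
    )
    if 0 not in means.columns or 1 not in means.columns:
        return None
    delta = (means[1] - means[0]).dropna()
    if not len(delta):
        return None
    transition = str(sub["transition"].iloc[0]) if "transition" in sub.columns else ""
    window_type = str(sub["window_type"].iloc[0]) if "window_type" in sub.columns else ""
    sd = float(np.std(delta, ddof=1)) if len(delta) > 1 else float("nan")
    return ChangeSummary(
        transition=transition,
        window_type=window_type,
        stratum=stratum,
        outcome=outcome,
        mean_change=float(delta.mean()),
        sd_change=sd,
        n=int(len(delta)),
    )


def change_summary_grid(
    panels: Sequence[pd.DataFrame],
    outcomes: Sequence[str] = ("exercise_minutes", "active_calories"),
) -> pd.DataFrame:
    """Change summaries for every panel x outcome x stratum combination."""
    rows: List[dict] = []
    for panel in panels:
        if panel is None or not len(panel):
            continue
        for outcome in outcomes:
            for stratum in STRATA:
                cs = person_level_change(panel, outcome, stratum)
                if cs is not None:
                    rows.append(cs.to_row())
    return pd.DataFrame(
        rows,
        columns=["transition", "window_type", "stratum", "outcome", "mean_change", "sd_change", "n"],
    )
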