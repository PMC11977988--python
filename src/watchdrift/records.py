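"""Core record tables and CSV interchange.

Three tidy tables flow through the pipeline, all UTF-8 comma-delimited CSV
with ISO-8601 dates/times:

* ``heart_rate.csv`` — one row per heart-rate measurement:
  ``participant_id, timestamp, bpm, source_version, product_type``.
  Timestamps are timezone-naive local instants: days are defined by the
  wearer's local calendar date.
* ``daily_activity.csv`` — one row per participant-day of outcomes:
  ``participant_id, date, exercise_minutes, active_calories``.
* ``participants.csv`` — ``participant_id, sex`` with sex in
  {``male``, ``female``} (required for the sex-specific percentile filter
  and stratified models).

Readers are forgiving about malformed *rows* (rejected and counted via
logging) but strict about *structure* (a missing column is a hard error
naming the column, conflicting duplicate activity rows are a hard error).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

HEART_RATE_COLUMNS = ["participant_id", "timestamp", "bpm", "source_version", "product_type"]
ACTIVITY_COLUMNS = ["participant_id", "date", "exercise_minutes", "active_calories"]
PARTICIPANT_COLUMNS = ["participant_id", "sex"]
OUTCOMES = ["exercise_minutes", "active_calories"]
SEXES = ("female", "male")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def read_heart_rate_csv(path: PathLike) -> pd.DataFrame:
    """Read minute-level heart-rate records.

    Returns a DataFrame sorted by (participant_id, timestamp) with exact
    duplicate rows dropped.  Rows with unparseable timestamps or
    non-positive bpm are rejected and counted in the log.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, HEART_RATE_COLUMNS, path)
    n_raw = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bpm = pd.to_numeric(df["bpm"], errors="coerce")
    bad = ts.isna() | bpm.isna() | (bpm <= 0) | df["participant_id"].isna()
    if bad.any():
        logger.warning("read_heart_rate_csv: rejected %d malformed rows of %d", int(bad.sum()), n_raw)
    out = pd.DataFrame(
        {
            "participant_id": df.loc[~bad, "participant_id"].astype(str),
            "timestamp": ts[~bad],
            "bpm": bpm[~bad].astype(float),
            "source_version": df.loc[~bad, "source_version"].fillna("").astype(str),
            "product_type": df.loc[~bad, "product_type"].fillna("").astype(str),
        }
    )
    n_before = len(out)
    out = out.drop_duplicates()
    if len(out) < n_before:
        logger.info("read_heart_rate_csv: dropped %d exact duplicates", n_before - len(out))
    out = out.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return out


def read_daily_activity_csv(path: PathLike) -> pd.DataFrame:
    """Read daily activity summaries (one row per participant-day).

    Identical duplicate rows collapse to one; duplicates with conflicting
    outcome values are a hard error.  Rows with negative outcomes are
    rejected and counted.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ACTIVITY_COLUMNS, path)
    date = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    ex = pd.to_numeric(df["exercise_minutes"], errors="coerce")
    cal = pd.to_numeric(df["active_calories"], errors="coerce")
    bad = date.isna() | ex.isna() | cal.isna() | (ex < 0) | (cal < 0) | df["participant_id"].isna()
    if bad.any():
        logger.warning("read_daily_activity_csv: rejected %d malformed rows of %d", int(bad.sum()), len(df))
    out = pd.DataFrame(
        {
            "participant_id": df.loc[~bad, "participant_id"].astype(str),
            "date": date[~bad].dt.normalize(),
            "exercise_minutes": ex[~bad].astype(float),
            "active_calories": cal[~bad].astype(float),
        }
    ).drop_duplicates()
    dup = out.duplicated(subset=["participant_id", "date"], keep=False)
    if dup.any():
        key = out.loc[dup, ["participant_id", "date"]].iloc[0]
        raise ValueError(
            f"{path}: conflicting duplicate activity rows, e.g. participant "
            f"{key['participant_id']!r} on {key['date'].date()}"
        )
    return out.sort_values(["participant_id", "date"], kind="mergesort").reset_index(drop=True)


def read_participants_csv(path: PathLike) -> pd.DataFrame:
    """Read participant metadata; every participant must carry a valid sex."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PARTICIPANT_COLUMNS, path)
    sex = df["sex"].str.strip().str.lower()
    invalid = ~sex.isin(SEXES)
    if invalid.any():
        raise ValueError(f"{path}: invalid sex values {sorted(df.loc[invalid, 'sex'].unique())}")
    out = pd.DataFrame({"participant_id": df["participant_id"].astype(str), "sex": sex})
    if out["participant_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated participant_id")
    return out.reset_index(drop=True)


def write_heart_rate_csv(df: pd.DataFrame, path: PathLike) -> None:
    out = df[HEART_RATE_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_daily_activity_csv(df: pd.DataFrame, path: PathLike) -> None:
    out = df[ACTIVITY_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_participants_csv(df: pd.DataFrame, path: PathLike) -> None:
    df[PARTICIPANT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model-results table

RESULT_COLUMNS = [
    "transition",
    "window_type",
    "stratum",
    "adjusted",
    "outcome",
    "rate_ratio",
    "ci_low",
    "ci_high",
    "formatted",
    "n_participants",
    "n_days",
    "alpha",
    "sigma_b_var",
    "loglike",
    "converged",
]


def format_rr(rr: float, lo: float, hi: float) -> str:
    """Render a rate ratio with its 95% CI at 2 decimals, e.g. '1.00 (0.92, 1.08)'."""
    if not np.isfinite(rr):
        return ""
    return f"{rr:.2f} ({lo:.2f}, {hi:.2f})"


def write_results_table(results: Union[pd.DataFrame, Iterable], path: PathLike) -> pd.DataFrame:
    """Write fitted rate ratios to CSV.

    Accepts either a tidy DataFrame with the RESULT_COLUMNS fields or an
    iterable of objects exposing them (``NBGLMMResult``).  The written table
    keeps full-precision numeric columns next to the 2-decimal formatted
    rendering, so it round-trips losslessly.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        rows = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in results]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("write_results_table: empty results collection")
    if "formatted" not in df.columns:
        df["formatted"] = [
            format_rr(r, lo, hi) for r, lo, hi in zip(df["rate_ratio"], df["ci_low"], df["ci_high"])
        ]
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    df = df[cols + [c for c in df.columns if c not in cols]]
    df.to_csv(path, index=False)
    return df


def read_results_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "converged" in df.columns:
        df["converged"] = df["converged"].astype(bool)
    return df
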