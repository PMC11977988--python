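"""Version parsing and day-level version assignment.

Software exposure is the *major* operating-system version (the integer
before the first dot of the raw version string): measurement behaviour is
assumed to change at major upgrades (e.g. 7 -> 8), not at minor updates
(7.3 -> 7.4).  Hardware exposure is the commercial generation name mapped
from the internal product identifier (e.g. ``Watch6,2`` -> ``Series 6``);
size and cellular variants of one generation collapse to the same name.
The mapping ships as an editable CSV (``data/hardware_index.csv``) because
the vendor extends it annually.

Both exposures are aggregated to the participant-day level using the mode
of that day's measurements.  Exact ties break toward the *newer* version:
numerically larger for software; for hardware (names are not totally
ordered across product lines) the candidate first seen later in that
participant's record stream wins.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Dict, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN_HARDWARE = "unknown"


class VersionParseError(ValueError):
    """Raised when a raw software version string has no leading integer."""


def parse_major_version(source_version: str) -> int:
    """Extract the major version: the integer before the first dot.

    >>> parse_major_version("7.3.1")
    7
    """
    token = str(source_version).strip().split(".", 1)[0]
    if not token.isdigit():
        raise VersionParseError(f"cannot parse major version from {source_version!r}")
    return int(token)


def load_hardware_index(path=None) -> Dict[str, str]:
    """Load the product-identifier -> commercial-name mapping.

    Uses the bundled table when ``path`` is omitted.  Every identifier maps
    to exactly one name (duplicated identifiers are a hard error).
    """
    if path is None:
        with resources.files("watchdrift").joinpath("data/hardware_index.csv").open("rb") as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    for col in ("product_type", "commercial_name"):
        if col not in df.columns:
            raise ValueError(f"hardware index: missing column {col!r}")
    if df["product_type"].duplicated().any():
        dup = df.loc[df["product_type"].duplicated(), "product_type"].iloc[0]
        raise ValueError(f"hardware index: identifier {dup!r} maps to more than one name")
    return dict(zip(df["product_type"], df["commercial_name"]))


def map_hardware(product_type: str, index: Dict[str, str]) -> str:
    """Map one identifier to its commercial name, or the 'unknown' sentinel."""
    return index.get(str(product_type), UNKNOWN_HARDWARE)


def _parsed_versions(heart_rate: pd.DataFrame, index: Optional[Dict[str, str]]) -> pd.DataFrame:
    """Internal: per-record parsed major version and hardware name."""
    if index is None:
        index = load_hardware_index()
    major = heart_rate["source_version"].astype(str).str.extract(r"^\s*(\d+)", expand=False)
    n_bad = int(major.isna().sum())
    if n_bad:
        logger.warning("day_version_counts: %d records with unparseable software version excluded", n_bad)
    hw = heart_rate["product_type"].map(index).fillna(UNKNOWN_HARDWARE)
    n_unk = int((hw == UNKNOWN_HARDWARE).sum())
    if n_unk:
        logger.warning("day_version_counts: %d records with unknown hardware identifier", n_unk)
    return pd.DataFrame(
        {
            "participant_id": heart_rate["participant_id"],
            "date": heart_rate["timestamp"].dt.normalize(),
            "major_software": pd.to_numeric(major, errors="coerce").astype("Int64"),
            "hardware_name": hw,
        }
    )


def day_version_counts(
    heart_rate: pd.DataFrame, index: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Per participant-day measurement counts for each observed version.

    Returns a long table ``participant_id, date, kind, version, n`` with
    ``kind`` in {'software', 'hardware'}.  Software versions are stringified
    integers; records with unparseable version strings are excluded from the
    software counts.  Unknown hardware identifiers count under the
    'unknown' sentinel (such days are excluded from hardware analyses).
    """
    parsed = _parsed_versions(heart_rate, index)
    sw = parsed.dropna(subset=["major_software"])
    sw_counts = (
        sw.groupby(["participant_id", "date", "major_software"], sort=True, observed=True)
        .size()
        .reset_index(name="n")
    )
    sw_counts["version"] = sw_counts.pop("major_software").astype(int).astype(str)
    sw_counts["kind"] = "software"
    hw_counts = (
        parsed.groupby(["participant_id", "date", "hardware_name"], sort=True, observed=True)
        .size()
        .reset_index(name="n")
    )
    hw_counts["version"] = hw_counts.pop("hardware_name")
    hw_counts["kind"] = "hardware"
    cols = ["participant_id", "date", "kind", "version", "n"]
    return pd.concat([sw_counts[cols], hw_counts[cols]], ignore_index=True)


def _hardware_recency(heart_rate: pd.DataFrame, index: Optional[Dict[str, str]]) -> pd.DataFrame:
    """First appearance order of each hardware name per participant (for ties)."""
    parsed = _parsed_versions(heart_rate, index)
    known = parsed[parsed["hardware_name"] != UNKNOWN_HARDWARE]
    first = (
        known.assign(ts=heart_rate["timestamp"])
        .groupby(["participant_id", "hardware_name"], sort=True)["ts"]
        .min()
        .reset_index(name="first_seen")
    )
    return first


def assign_day_versions(
    heart_rate: pd.DataFrame, index: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Assign one modal software and hardware version per participant-day.

    Returns ``participant_id, date, n_measurements, major_software,
    software_share, hardware_name, hardware_share``.  ``software_share`` is
    the fraction of the day's version-parseable measurements carried by the
    winning major version (analogously for hardware over known-hardware
    measurements).  Days whose measurements are all unparseable (software)
    or all unknown (hardware) get a missing value for that exposure.
    """
    if index is None:
        index = load_hardware_index()
    counts = day_version_counts(heart_rate, index)
    totals = (
        heart_rate.assign(date=heart_rate["timestamp"].dt.normalize())
        .groupby(["participant_id", "date"], sort=True)
        .size()
        .reset_index(name="n_measurements")
    )

    sw = counts[counts["kind"] == "software"].copy()
    sw["rank"] = sw["version"].astype(int)
    sw_tot = sw.groupby(["participant_id", "date"])["n"].transform("sum")
    sw["share"] = sw["n"] / sw_tot
    sw = sw.sort_values(["participant_id", "date", "n", "rank"], kind="mergesort")
    sw_win = sw.groupby(["participant_id", "date"], sort=True).tail(1)
    sw_win = sw_win.rename(columns={"version": "major_software", "share": "software_share"})
    sw_win["major_software"] = sw_win["major_software"].astype(int)

    hw = counts[(counts["kind"] == "hardware") & (counts["version"] != UNKNOWN_HARDWARE)].copy()
    recency = _hardware_recency(heart_rate, index)
    rank_map = {
        (r.participant_id, r.hardware_name): i
        for i, r in enumerate(recency.sort_values(["participant_id", "first_seen"]).itertuples())
    }
    hw["rank"] = [rank_map.get((p, v), -1) for p, v in zip(hw["participant_id"], hw["version"])]
    hw_tot = hw.groupby(["participant_id", "date"])["n"].transform("sum")
    hw["share"] = hw["n"] / hw_tot
    hw = hw.sort_values(["participant_id", "date", "n", "rank"], kind="mergesort")
    hw_win = hw.groupby(["participant_id", "date"], sort=True).tail(1)
    hw_win = hw_win.rename(columns={"version": "hardware_name", "share": "hardware_share"})

    out = totals.merge(
        sw_win[["participant_id", "date", "major_software", "software_share"]],
        on=["participant_id", "date"],
        how="left",
    ).merge(
        hw_win[["participant_id", "date", "hardware_name", "hardware_share"]],
        on=["participant_id", "date"],
        how="left",
    )
    out["major_software"] = out["major_software"].astype("Int64")
    return out.sort_values(["participant_id", "date"], kind="mergesort").reset_index(drop=True)
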