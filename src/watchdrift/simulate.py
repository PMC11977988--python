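"""Synthetic smartwatch cohorts with known ground truth.

The generator emulates the structure of a retrospective consumer-wearable
cohort: participants with sex-specific lognormal activity levels, daily
outcome counts drawn from an NB2 model with a participant random intercept
and weekday effects, annual software releases adopted 25-31 days later,
occasional hardware purchases, a small fraction of device alternators,
heart-rate sampling with exponential inter-measurement times (mean 5.62
minutes, truncated at 1 minute) inside a daily wear window, and missing
activity days.  Version-transition effects enter multiplicatively on the
outcome mean and switch exactly at the day the new version first carries a
strict majority of the day's heart-rate measurements -- the identifying
assumption of the pre/post design, which makes parameter-recovery tests
well-posed.

Records on the upgrade day itself are split between old and new version
according to the (random) time of day of the switch, so transition-date
detection is genuinely exercised.

By default heart-rate records are only emitted within ``hr_margin_days``
(25) of each true upgrade, merged across overlapping windows: days further
from every upgrade carry no information for any pipeline stage, and
full-span sampling at 5.62-minute cadence would be millions of rows per
cohort.  Set ``hr_margin_days=None`` for full-span sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

SOFTWARE = "software"
HARDWARE = "hardware"

# Published baseline-week mean (SD) of the daily outcomes, by sex.
DEFAULT_BASELINES = {
    "exercise_minutes": {
        "overall": (48.97, 34.05),
        "female": (48.15, 29.68),
        "male": (49.34, 35.92),
    },
    "active_calories": {
        "overall": (710.43, 250.62),
        "female": (594.31, 193.63),
        "male": (764.17, 255.92),
    },
}

# Day-to-day NB2 dispersion; not identified by the published summaries, chosen
# once as realistic within-person variability (see docs/methods.md).
DEFAULT_ALPHA = {"exercise_minutes": 0.30, "active_calories": 0.05}

DEFAULT_SOFTWARE_RELEASES = {
    6: "2019-09-19",
    7: "2020-09-16",
    8: "2021-09-20",
    9: "2022-09-12",
}
DEFAULT_HARDWARE_RELEASES = {
    "Series 5": "2019-09-20",
    "Series 6": "2020-09-18",
    "Series 7": "2021-10-15",
    "Series 8": "2022-09-16",
}

# True multiplicative transition effects, keyed by adopted software version
# (or 'hardware'); defaults are the published unadjusted overall estimates,
# which the recovery analyses treat as known truth.
DEFAULT_EFFECTS = {
    "exercise_minutes": {"6": 1.01, "7": 0.92, "8": 1.13, "9": 0.91, "hardware": 1.00},
    "active_calories": {"6": 0.99, "7": 0.96, "8": 1.00, "9": 0.97, "hardware": 0.99},
}

PRODUCT_VARIANTS = {
    "Series 3": ["Watch3,1", "Watch3,2", "Watch3,3", "Watch3,4"],
    "Series 4": ["Watch4,1", "Watch4,2", "Watch4,3", "Watch4,4"],
    "Series 5": ["Watch5,1", "Watch5,2", "Watch5,3", "Watch5,4"],
    "Series 6": ["Watch6,1", "Watch6,2", "Watch6,3", "Watch6,4"],
    "Series 7": ["Watch6,6", "Watch6,7", "Watch6,8", "Watch6,9"],
    "Series 8": ["Watch6,14", "Watch6,15", "Watch6,16", "Watch6,17"],
}

DEFAULT_WEEKDAY_MULTIPLIERS = (1.0, 1.0, 1.0, 1.0, 1.03, 1.10, 1.06)  # Mon..Sun


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with the study-like defaults."""

    n_participants: int = 250
    proportion_male: float = 0.61
    start_date: str = "2019-01-01"
    end_date: str = "2022-12-31"
    baselines: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BASELINES.items()}
    )
    sigma_b: Optional[Dict[str, float]] = None  # None: lognormal moment match
    alpha: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    weekday_multipliers: Tuple[float, ...] = DEFAULT_WEEKDAY_MULTIPLIERS
    effects: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    software_releases: Dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_SOFTWARE_RELEASES)
    )
    hardware_releases: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HARDWARE_RELEASES)
    )
    adoption_lag_days: Tuple[int, int] = (25, 31)
    p_adopt_software: float = 0.9
    p_adopt_hardware: float = 0.17
    p_alternator: float = 0.066
    hr_mean_gap_minutes: float = 5.62
    wear_start_hour: float = 7.0
    wear_end_hour: float = 23.0
    p_missing_day: float = 0.035
    hr_margin_days: Optional[int] = 25
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("proportion_male", "p_adopt_software", "p_adopt_hardware",
                     "p_alternator", "p_missing_day"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for outcome, eff in self.effects.items():
            for k, v in eff.items():
                if v <= 0:
                    raise ValueError(f"effect {outcome}/{k} must be > 0")


@dataclass
class Cohort:
    participants: pd.DataFrame
    heart_rate: pd.DataFrame
    activity: pd.DataFrame
    ground_truth: dict


def lognormal_sigma(mean: float, sd: float) -> float:
    """Log-scale SD of a lognormal with the given arithmetic mean and SD."""
    return float(np.sqrt(np.log1p((sd / mean) ** 2)))


def _sample_day_times(
    rng: np.random.Generator, n_days: int, wear_minutes: float, mean_gap: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Minutes-into-wear-window of each measurement, per day (flattened)."""
    n_max = int(wear_minutes / max(mean_gap, 1.0) * 1.5) + 30
    gaps = 1.0 + rng.exponential(mean_gap - 1.0, size=(n_days, n_max))
    times = np.cumsum(gaps, axis=1)
    mask = times < wear_minutes
    day_idx = np.repeat(np.arange(n_days), mask.sum(axis=1))
    return times[mask], day_idx


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> Cohort:
    """Generate (participants, heart-rate records, daily activity, ground truth)."""
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date)
    n_days_total = (end - start).days + 1
    all_days = start + pd.to_timedelta(np.arange(n_days_total), unit="D")
    wear_start_min = config.wear_start_hour * 60.0
    wear_minutes = (config.wear_end_hour - config.wear_start_hour) * 60.0
    lag_lo, lag_hi = config.adoption_lag_days

    sigma_b = {}
    for outcome in config.baselines:
        if config.sigma_b is not None and outcome in config.sigma_b:
            sigma_b[outcome] = config.sigma_b[outcome]
        else:
            m, s = config.baselines[outcome]["overall"]
            sigma_b[outcome] = lognormal_sigma(m, s)

    participants = []
    hr_frames = []
    act_frames = []
    upgrades_ledger: List[dict] = []
    alternators: List[str] = []

    sw_releases = sorted(
        (int(v), pd.Timestamp(d)) for v, d in config.software_releases.items()
    )
    hw_releases = sorted(
        ((g, pd.Timestamp(d)) for g, d in config.hardware_releases.items()),
        key=lambda x: x[1],
    )

    for i in range(config.n_participants):
        pid = f"P{i + 1:04d}"
        sex = "male" if rng.random() < config.proportion_male else "female"
        participants.append({"participant_id": pid, "sex": sex})

        # --- software adoption timeline -----------------------------------
        sw_switches: List[dict] = []  # switch datetime, from, to
        current_sw = min(v for v, _ in sw_releases) - 1
        for v, rel in sw_releases:
            if rel < start or rel > end - pd.Timedelta(days=40):
                continue
            if rng.random() >= config.p_adopt_software:
                continue
            up_date = rel + pd.Timedelta(days=int(rng.integers(lag_lo, lag_hi + 1)))
            tod = wear_start_min + rng.uniform(0, wear_minutes)
            sw_switches.append(
                {
                    "when": up_date + pd.Timedelta(minutes=tod),
                    "from": str(current_sw),
                    "to": str(v),
                }
            )
            current_sw = v

        # --- hardware timeline --------------------------------------------
        is_alternator = rng.random() < config.p_alternator
        gens = list(PRODUCT_VARIANTS)
        initial_gen = gens[int(rng.integers(0, 2))]  # Series 3 or 4
        hw_switches: List[dict] = []
        alt_devices = None
        if is_alternator:
            alternators.append(pid)
            alt_devices = (initial_gen, gens[gens.index(initial_gen) + 1])
        else:
            current_hw = initial_gen
            for gen, rel in hw_releases:
                if rel < start or rel > end - pd.Timedelta(days=40):
                    continue
                if rng.random() >= config.p_adopt_hardware:
                    continue
                up_date = rel + pd.Timedelta(days=int(rng.integers(lag_lo, lag_hi + 1)))
                tod = wear_start_min + rng.uniform(0, wear_minutes)
                hw_switches.append(
                    {
                        "when": up_date + pd.Timedelta(minutes=tod),
                        "from": current_hw,
                        "to": gen,
                    }
                )
                current_hw = gen

        # --- covered days for heart-rate emission -------------------------
        switch_dates = [s["when"].normalize() for s in sw_switches + hw_switches]
        if config.hr_margin_days is None:
            covered = np.arange(n_days_total)
        else:
            mask = np.zeros(n_days_total, dtype=bool)
            m = config.hr_margin_days
            for d in switch_dates:
                lo = max(0, (d - start).days - m)
                hi = min(n_days_total, (d - start).days + m + 1)
                mask[lo:hi] = True
            if not mask.any():
                mask[: min(30, n_days_total)] = True
            covered = np.nonzero(mask)[0]
        cov_days = all_days[covered]

        # --- heart-rate records -------------------------------------------
        t_in_window, day_idx = _sample_day_times(
            rng, len(covered), wear_minutes, config.hr_mean_gap_minutes
        )
        ts = (
            cov_days[day_idx].to_numpy()
            + ((wear_start_min + t_in_window) * 60.0e9).astype("timedelta64[ns]")
        )
        n_rec = len(ts)

        # software stamping: step function over switch datetimes
        sw_versions = [s["from"] for s in sw_switches] + (
            [sw_switches[-1]["to"]] if sw_switches else [str(current_sw)]
        )
        minor = {
            v: f"{v}.{rng.integers(0, 7)}.{rng.integers(0, 4)}"
            for v in {s["from"] for s in sw_switches}
            | {s["to"] for s in sw_switches}
            | {str(current_sw)}
        }
        if sw_switches:
            cut = np.array([s["when"].to_datetime64() for s in sw_switches])
            sw_idx = np.searchsorted(cut, ts, side="right")
            source_version = np.array([minor[v] for v in sw_versions], dtype=object)[sw_idx]
        else:
            source_version = np.full(n_rec, minor[str(current_sw)], dtype=object)

        # hardware stamping
        variant = {
            gen: PRODUCT_VARIANTS[gen][int(rng.integers(0, len(PRODUCT_VARIANTS[gen])))]
            for gen in PRODUCT_VARIANTS
        }
        if is_alternator:
            # alternate devices in blocks of 2-6 days over the whole span
            block_lens = rng.integers(2, 7, size=n_days_total // 2 + 2)
            block_starts = np.concatenate(([0], np.cumsum(block_lens)))
            day_numbers = covered[day_idx]
            block_of_day = np.searchsorted(block_starts, day_numbers, side="right") - 1
            dev = np.where(block_of_day % 2 == 0, variant[alt_devices[0]], variant[alt_devices[1]])
            product_type = dev.astype(object)
        elif hw_switches:
            cut = np.array([s["when"].to_datetime64() for s in hw_switches])
            hw_gens = [s["from"] for s in hw_switches] + [hw_switches[-1]["to"]]
            hw_idx = np.searchsorted(cut, ts, side="right")
            product_type = np.array([variant[g] for g in hw_gens], dtype=object)[hw_idx]
        else:
            product_type = np.full(n_rec, variant[initial_gen], dtype=object)

        bpm = np.clip(rng.normal(75.0, 12.0, size=n_rec), 40.0, None).round(0)
        hr_frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.full(n_rec, pid, dtype=object),
                    "timestamp": ts,
                    "bpm": bpm,
                    "source_version": source_version,
                    "product_type": product_type,
                }
            )
        )

        # --- ground-truth transition dates (generator-side bookkeeping) ----
        rec_day = (ts.astype("datetime64[D]") - start.to_datetime64().astype("datetime64[D]")).astype(int)
        day_total = np.bincount(rec_day, minlength=n_days_total)

        def _majority_date(when: pd.Timestamp, new_mask: np.ndarray) -> Optional[pd.Timestamp]:
            d0 = (when.normalize() - start).days
            day_new = np.bincount(rec_day, weights=new_mask.astype(float), minlength=n_days_total)
            for d in range(d0, n_days_total):
                if day_total[d] > 0:
                    if 2 * day_new[d] > day_total[d]:
                        return start + pd.Timedelta(days=d)
                    if day_new[d] == 0 and d > d0:
                        return None  # should not happen for monotone switches
            return None

        for s in sw_switches:
            mdate = _majority_date(s["when"], ts >= s["when"].to_datetime64())
            upgrades_ledger.append(
                {
                    "participant_id": pid,
                    "kind": SOFTWARE,
                    "from_version": s["from"],
                    "to_version": s["to"],
                    "switch_datetime": str(s["when"]),
                    "transition_date": str(mdate.date()) if mdate is not None else None,
                    "effects": {
                        o: config.effects[o].get(s["to"], 1.0) for o in config.effects
                    },
                }
            )
        for s in hw_switches:
            mdate = _majority_date(s["when"], ts >= s["when"].to_datetime64())
            upgrades_ledger.append(
                {
                    "participant_id": pid,
                    "kind": HARDWARE,
                    "from_version": s["from"],
                    "to_version": s["to"],
                    "switch_datetime": str(s["when"]),
                    "transition_date": str(mdate.date()) if mdate is not None else None,
                    "effects": {
                        o: config.effects[o].get("hardware", 1.0) for o in config.effects
                    },
                }
            )

        # --- daily activity outcomes --------------------------------------
        z = rng.standard_normal()  # shared activity frailty across outcomes
        weekday = pd.DatetimeIndex(all_days).dayofweek.to_numpy()
        log_wd = np.log(np.asarray(config.weekday_multipliers))[weekday]
        missing = rng.random(n_days_total) < config.p_missing_day
        outcome_values = {}
        for outcome, strata in config.baselines.items():
            mean_s, _ = strata[sex]
            sb = sigma_b[outcome]
            intercept = np.log(mean_s) - 0.5 * sb * sb + sb * z
            log_mu = intercept + log_wd
            for u in upgrades_ledger:
                if u["participant_id"] != pid or u["transition_date"] is None:
                    continue
                key = u["to_version"] if u["kind"] == SOFTWARE else "hardware"
                eff = config.effects[outcome].get(key, 1.0)
                d = (pd.Timestamp(u["transition_date"]) - start).days
                log_mu = log_mu + np.log(eff) * (np.arange(n_days_total) >= d)
            mu = np.exp(log_mu)
            a = config.alpha[outcome]
            lam = mu * rng.gamma(1.0 / a, a, size=n_days_total)
            outcome_values[outcome] = rng.poisson(lam).astype(float)
        act_frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.full((~missing).sum(), pid, dtype=object),
                    "date": all_days[~missing],
                    "exercise_minutes": outcome_values["exercise_minutes"][~missing],
                    "active_calories": outcome_values["active_calories"][~missing],
                }
            )
        )

    heart_rate = pd.concat(hr_frames, ignore_index=True)
    heart_rate = heart_rate.sort_values(
        ["participant_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    activity = pd.concat(act_frames, ignore_index=True)
    ground_truth = {
        "seed": config.seed,
        "alternators": alternators,
        "upgrades": upgrades_ledger,
        "sigma_b": sigma_b,
        "alpha": dict(config.alpha),
        "effects": {k: dict(v) for k, v in config.effects.items()},
    }
    return Cohort(
        participants=pd.DataFrame(participants),
        heart_rate=heart_rate,
        activity=activity,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Direct panel simulation (for model-level recovery studies)


def simulate_panel(
    n_participants: int,
    true_rr: float,
    outcome: str = "exercise_minutes",
    baseline: Optional[Tuple[float, float]] = None,
    alpha: Optional[float] = None,
    sigma_b: Optional[float] = None,
    weekday_multipliers: Optional[Tuple[float, ...]] = None,
    window_type: str = "treatment",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate one 14-day pre/post panel directly from the NB2 mixed model.

    Participant log-intercepts are lognormal moment-matched to the given
    baseline mean/SD (defaults: the published overall baselines for the
    outcome); the multiplicative effect ``true_rr`` switches on exactly at
    the transition date.  For ``window_type='control'`` no effect is active
    (both weeks precede the upgrade), so the true RR there is 1.

    Returns a panel table ready for :func:`watchdrift.nbglmm.fit_nb_glmm`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = DEFAULT_BASELINES[outcome]["overall"]
    if alpha is None:
        alpha = DEFAULT_ALPHA[outcome]
    mean, sd = baseline
    if sigma_b is None:
        sigma_b = lognormal_sigma(mean, sd)
    if weekday_multipliers is None:
        weekday_multipliers = DEFAULT_WEEKDAY_MULTIPLIERS
    log_wd = np.log(np.asarray(weekday_multipliers))

    base_date = pd.Timestamp("2021-09-20")
    offsets = np.arange(-7, 7) if window_type == "treatment" else np.arange(-14, 0)
    post = (offsets >= 0).astype(int) if window_type == "treatment" else (offsets >= -7).astype(int)

    intercepts = np.log(mean) - 0.5 * sigma_b**2 + sigma_b * rng.standard_normal(n_participants)
    tdates = base_date + pd.to_timedelta(rng.integers(0, 21, size=n_participants), unit="D")
    sexes = np.where(rng.random(n_participants) < 0.61, "male", "female")

    rows = []
    for p in range(n_participants):
        dates = tdates[p] + pd.to_timedelta(offsets, unit="D")
        dow = pd.DatetimeIndex(dates).dayofweek.to_numpy()
        effect_on = post if window_type == "treatment" else np.zeros_like(post)
        log_mu = intercepts[p] + log_wd[dow] + np.log(true_rr) * effect_on
        mu = np.exp(log_mu)
        lam = mu * rng.gamma(1.0 / alpha, alpha, size=len(mu))
        y = rng.poisson(lam).astype(float)
        for k in range(len(offsets)):
            rows.append(
                (
                    "simulated",
                    window_type,
                    f"S{p + 1:04d}",
                    tdates[p],
                    dates[k],
                    int(offsets[k]),
                    int(post[k]),
                    dates[k].day_name(),
                    y[k],
                    sexes[p],
                )
            )
    panel = pd.DataFrame(
        rows,
        columns=[
            "transition",
            "window_type",
            "participant_id",
            "transition_date",
            "date",
            "day_offset",
            "post",
            "weekday",
            outcome,
            "sex",
        ],
    )
    other = "active_calories" if outcome == "exercise_minutes" else "exercise_minutes"
    panel[other] = 0.0
    return panel


# ---------------------------------------------------------------------------
# Worked toy fixture


@dataclass
class WorkedToy:
    participants: pd.DataFrame
    heart_rate: pd.DataFrame
    activity: pd.DataFrame
    expected_wear: pd.DataFrame  # hand-computed rows for designated days
    expected_transition_date: pd.Timestamp
    expected_eligible_events: int
    expected_reason_counts: Dict[str, int]


def _grid_times(date: pd.Timestamp, spec: List[Tuple[str, str, float]]) -> List[pd.Timestamp]:
    """Sampling instants for one day: list of (start, end, step-minutes) blocks.

    Blocks are [start, end) on a regular step; times are offsets from the
    day's midnight expressed as 'HH:MM' or 'HH:MM:SS'.
    """
    def _td(s: str) -> pd.Timedelta:
        return pd.Timedelta(s if s.count(":") == 2 else s + ":00")

    out = []
    day = date.normalize()
    for t0, t1, step in spec:
        a = day + _td(t0)
        b = day + _td(t1)
        t = a
        while t < b:
            out.append(t)
            t = t + pd.Timedelta(minutes=step)
    return out


def generate_worked_toy() -> WorkedToy:
    """Hand-designed 4-participant fixture exercising every pipeline rule.

    * ``anna`` (female): clean watchOS 7 -> 8 transition on 2021-09-20 (the
      day before is an exact 50/50 split, so the strict-majority rule must
      skip it) plus hand-checkable wear-time days: a 40.0-minute gap
      (inclusive threshold), a 39.9-minute gap (no segment), an overnight
      23:30-01:30 gap split 30/90 at midnight, and a day with exactly 600
      wear minutes (retained: only "under 600" is excluded).  Her event is
      the fixture's single eligible transition.
    * ``carl`` (male): device alternator, Series 6 -> 7 on 09-15 and back on
      09-22 with activity data starting only on 09-15, so his first
      hardware event lacks a pre-week (missing_week) and his second sees
      two hardware changes (multiple_hardware_changes).
    * ``dave`` (male): watchOS 5 -> 7 jump (non_consecutive).
    * ``erin`` (female): hardware swap on 09-14, watchOS 6 -> 7 on 09-17 and
      7 -> 8 on 09-24; her first software event has the swap in window
      (hardware_change_in_window), her second sees two software changes
      (multiple_software_changes), and her hardware event sees a software
      change in window (software_change_in_window).

    Each of the six exclusion reasons fires exactly once.  Outcomes follow
    small cyclic patterns whose maxima are tied, so the sex-specific
    99.9th-percentile filter removes no day.
    """
    start = pd.Timestamp("2021-09-01")
    n_days = 40
    days = start + pd.to_timedelta(np.arange(n_days), unit="D")
    dense = [("00:00", "24:00", 5.0)]  # 288 samples, wear 1440

    participants = pd.DataFrame(
        {
            "participant_id": ["anna", "carl", "dave", "erin"],
            "sex": ["female", "male", "male", "female"],
        }
    )

    hr_rows = []  # (pid, timestamp, source_version, product_type)

    def emit(pid, date, blocks, version_fn, product_fn):
        times = _grid_times(date, blocks)
        for k, t in enumerate(times):
            hr_rows.append((pid, t, version_fn(k, len(times), t), product_fn(t)))

    # --- anna ---------------------------------------------------------------
    special = {
        "2021-09-02": [("00:00", "13:00:01", 5.0), ("13:40", "24:00", 5.0)],
        "2021-09-03": [("00:00", "13:00:01", 5.0), ("13:39:54", "24:00", 5.0)],
        "2021-09-04": [("00:00", "23:30:01", 5.0)],
        "2021-09-05": [("01:30", "24:00", 5.0)],
        "2021-09-06": [
            ("00:00", "02:00:01", 5.0),  # 10h gap to 12:00, then a 4h gap:
            ("12:00", "16:00:01", 5.0),  # 600 + 240 = 840 non-wear, wear 600
            ("20:00", "24:00", 5.0),
        ],
    }

    def anna_version(k, n, t):
        d = t.normalize()
        if d < pd.Timestamp("2021-09-19"):
            return "7.6.1"
        if d == pd.Timestamp("2021-09-19"):
            return "7.6.1" if k < n // 2 else "8.0"  # exact 144/144 tie
        if d == pd.Timestamp("2021-09-20"):
            return "7.6.1" if k < 115 else "8.0"  # 173/288 new: strict majority
        return "8.0"

    for d in days:
        blocks = special.get(str(d.date()), dense)
        emit("anna", d, blocks, anna_version, lambda t: "Watch6,2")

    # --- carl: alternator, constant software --------------------------------
    def carl_product(t):
        d = t.normalize()
        if d < pd.Timestamp("2021-09-15"):
            return "Watch6,1"  # Series 6
        if d < pd.Timestamp("2021-09-22"):
            return "Watch6,7"  # Series 7
        return "Watch6,1"

    for d in days:
        emit("carl", d, dense, lambda k, n, t: "8.4.1", carl_product)

    # --- dave: 5 -> 7 jump ---------------------------------------------------
    def dave_version(k, n, t):
        return "5.3" if t.normalize() < pd.Timestamp("2021-09-20") else "7.1"

    for d in days:
        emit("dave", d, dense, dave_version, lambda t: "Watch5,9")

    # --- erin: double software change + hardware swap ------------------------
    def erin_version(k, n, t):
        d = t.normalize()
        if d < pd.Timestamp("2021-09-17"):
            return "6.2.1"
        if d < pd.Timestamp("2021-09-24"):
            return "7.3.1"
        return "8.1"

    def erin_product(t):
        return "Watch5,1" if t.normalize() < pd.Timestamp("2021-09-14") else "Watch6,2"

    for d in days:
        emit("erin", d, dense, erin_version, erin_product)

    heart_rate = pd.DataFrame(
        hr_rows, columns=["participant_id", "timestamp", "source_version", "product_type"]
    )
    heart_rate["bpm"] = 70.0 + (np.arange(len(heart_rate)) % 30)
    heart_rate = heart_rate[
        ["participant_id", "timestamp", "bpm", "source_version", "product_type"]
    ].sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    # --- daily activity: cyclic, tied maxima, no outliers --------------------
    act_rows = []
    for pid in participants["participant_id"]:
        for j, d in enumerate(days):
            if pid == "carl" and d < pd.Timestamp("2021-09-15"):
                continue  # carl's activity starts with his first device swap
            act_rows.append(
                (pid, d, float(35 + 5 * (j % 7)), float(600 + 20 * (j % 5)))
            )
    activity = pd.DataFrame(
        act_rows, columns=["participant_id", "date", "exercise_minutes", "active_calories"]
    )

    expected_wear = pd.DataFrame(
        {
            "participant_id": "anna",
            "date": pd.to_datetime(
                ["2021-09-02", "2021-09-03", "2021-09-04", "2021-09-05", "2021-09-06"]
            ),
            "nonwear_minutes": [40.0, 0.0, 30.0, 90.0, 840.0],
            "wear_minutes": [1400.0, 1440.0, 1410.0, 1350.0, 600.0],
            "valid_day": [True, True, True, True, True],
        }
    )

    return WorkedToy(
        participants=participants,
        heart_rate=heart_rate,
        activity=activity,
        expected_wear=expected_wear,
        expected_transition_date=pd.Timestamp("2021-09-20"),
        expected_eligible_events=1,
        expected_reason_counts={
            "non_consecutive": 1,
            "multiple_software_changes": 1,
            "hardware_change_in_window": 1,
            "software_change_in_window": 1,
            "multiple_hardware_changes": 1,
            "missing_week": 1,
        },
    )
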