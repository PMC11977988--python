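# Methods

## The estimand and the design

When a smartwatch's operating system or hardware changes, its activity
algorithms may change with it.  The package estimates, per version
transition, the multiplicative shift in a daily activity count attributable
to the upgrade, as a rate ratio (RR) comparing the 7 days before a
participant's transition date with the 7 days after (inclusive of) it.
Because each participant upgrades on their own date, the 14-day window is
participant-specific; using whole weeks on both sides balances day-of-week
composition.  A control analysis applies the identical machinery to the two
fully pre-upgrade weeks (offsets −14..−8 vs −7..−1), where the true effect
is 1 by construction; it estimates ordinary week-to-week variability and
guards against trends.

The identifying assumption is that the measurement effect switches on
exactly at the transition date and that behaviour is otherwise stable
across the window.  The synthetic-data generator encodes exactly this
assumption, which is what makes parameter-recovery testing well-posed — and
is also why a green recovery test validates the estimator, not the
assumption.

## Wear time from heart-rate gaps

The watch records heart rate only while worn (roughly every 5.6 minutes on
average), so long sampling gaps indicate non-wear.  Rules, fixed after the
classic off-by-one traps:

* threshold 40 minutes, **inclusive** ("40 minutes or longer");
* the analysis range per participant runs from their first to last date
  with any data; range boundaries (midnight) act as virtual measurements,
  so a late first measurement on the first day creates a leading gap;
* segments are split at midnight and each part attributed to its own date,
  preserving wear + non-wear = 1440 exactly per day;
* valid wear day ⇔ wear ≥ 600 minutes (only "under 600" is excluded, so a
  600.0-minute day is retained);
* a covered date with no measurements at all lies inside one long segment
  and gets wear 0 (an invalid day, not a missing one); a date with no heart
  rate and no activity record is simply missing.

The segment algorithm is verified against a brute-force minute-grid
simulation on random instances.

## Person-day filters

Outlier thresholds are the 99.9th percentile (linear interpolation between
order statistics) of each outcome over **all** recorded person-days of each
sex, computed once before wear filtering.  A day is dropped when an outcome
is **strictly above** its threshold, when wear < 600 min, or when no wear
record exists.  Strictly-above rather than at-or-above: with an
interpolated quantile the per-stratum maximum always sits at or above the
threshold, so an at-or-above rule can never pass a "no outliers present"
fixture; on continuous data the two readings both remove ~0.1% of days and
differ only on ties.  Filtering is idempotent and each removal is logged
with its reasons.

## Day-level versions and transitions

Software exposure is the major version (integer before the first dot);
minor updates are deliberately ignored.  Hardware exposure is the
commercial generation mapped from the product identifier through an
editable CSV (sizes and cellular variants merge; unknown identifiers map to
a counted `unknown` sentinel and such days drop out of hardware analyses).
Both are aggregated per participant-day by the mode of that day's
measurements, ties breaking toward the newer version — numerically newer
for software; for hardware, whose names are not totally ordered, the
candidate first seen later in that participant's stream.

The transition date is the first day on which strictly more than half of
the day's measurements carry the new version ("most" = majority; strictness
keeps an exactly-tied day from qualifying).  Eligibility rules accumulate
reasons rather than short-circuiting:

* software events: from→to must be consecutive (5→6 … 8→9); excluded for a
  second software change in the window, any hardware change in the window,
  or an empty week;
* hardware events: excluded for any software change in the window, more
  than the single hardware change (the pre-week must be entirely old
  hardware and the post-week entirely new), or an empty week;
* "empty week" is evaluated on the *filtered* activity table, so a week of
  invalid-wear days counts as empty.  The ordering filters-then-eligibility
  is fixed and documented here because the alternative is equally readable
  from the source material.

Panels require ≥ `completeness_days` activity days per half-window: 7 (all
14 days) for the primary analysis, {1, 4, 5, 6} for sensitivity reruns
(descriptives at all four, models at 1).  When a participant has several
eligible events with one label, only the earliest is used, so a single
random intercept per participant is well-defined.

## The NB2 mixed model

Daily counts are modelled as NB2 (Var = μ + αμ²; the standard
epidemiological parameterization matching rate-ratio reporting) with a
log link, a binary pre/post term, optional 6 weekday contrasts (reference =
the panel's modal transition weekday, making β₁ interpretable at that
weekday; configurable), and a Normal random intercept per participant.
Outcomes are rounded to the nearest integer for the count likelihood
(calories are large counts; the rounding error is negligible).

The marginal likelihood integrates the intercept out by **adaptive**
Gauss–Hermite quadrature: per participant, a damped Newton search finds the
mode of the joint log-density in b (globally concave), the integrand is
re-centred and re-scaled by the curvature there, and a 9-node rule is
applied in log space.  Estimates are stable to < 1e-3 against 15 nodes.
Optimization is L-BFGS-B on (β, log α, log σ_b) from fixed starts (Poisson
GLM for β, α = 1, σ_b = 0.5), relative tolerance ~1e-11, with box bounds
log α ∈ [−12, 5] and log σ_b ∈ [−9, 3].  Standard errors come from a
central-difference Hessian of the negative log marginal likelihood;
variance parameters pinned at their lower bound (the σ_b → 0 plain-NB
limit) are profiled out of the Hessian.  CIs are 95% Wald on log RR — the
published intervals are consistent with symmetric log-scale intervals — and
are withheld when the fit has not converged.  Dispersion α is re-estimated
per model cell, including per sex stratum.

In the σ_b = 0 limit the model must agree with an ordinary NB2 regression;
the test suite checks this against an independent maximum-likelihood fit to
1e-3 on all coefficients, keeping the dual-route check intact.

## The synthetic cohort

The generator states a world matching the published cohort description and
does not move with test outcomes:

* 250 participants by default, 61% male, span 2019-01-01 – 2022-12-31;
* participant baselines are lognormal with the published per-sex week-mean
  and SD of each outcome (exercise overall 48.97 ± 34.05 min; calories
  710.43 ± 250.62 kcal); the log-scale intercept SD is the lognormal
  moment match σ_b = √log(1 + (SD/mean)²) (≈ 0.63 exercise, 0.35
  calories).  That published SD mixes between-person spread with weekly
  sampling noise, so this choice slightly overstates heterogeneity — the
  conservative direction for recovery tests;
* NB2 day-to-day dispersion α = 0.30 (exercise) and 0.05 (calories): not
  identified by any published summary; chosen once as realistic
  within-person variability (day SD ≈ 28 min at a 49-min mean; ≈ 160 kcal
  at 710), and RR recovery is insensitive to it;
* annual software releases (versions 6–9, each September) adopted with
  probability 0.9 at a uniform 25–31-day lag; hardware generations adopted
  with annual probability 0.17; 6.6% of participants are device
  alternators who switch between two devices in 2–6-day blocks;
* true multiplicative effects default to the published unadjusted overall
  rate ratios per transition and switch on exactly at the first
  strict-majority day; weekday multipliers default to a mild weekend bump;
* heart-rate sampling: 1 + Exponential(4.62) minute gaps (mean 5.62,
  truncated at 1) inside a 07:00–23:00 wear window, giving ~480 overnight
  non-wear minutes and valid wear days; upgrades switch at a uniform random
  time of the wear day, so the upgrade day's records are split between old
  and new version and majority detection is genuinely exercised;
* 3.5% of activity days are missing (chosen so that ~60% of eligible
  windows are 14/14-complete, matching the published accounting);
* heart-rate records are emitted only within 25 days of each true upgrade
  (merged windows) by default: days further out carry no information for
  any stage (panels use ±21 days; percentile thresholds use the full-span
  daily activity table), and full-span 5.6-minute sampling over four years
  would be tens of millions of rows.  `hr_margin_days=None` restores
  full-span emission.  One visible consequence: out-of-window days have no
  wear record and appear in the exclusion ledger, which is harmless
  because no analysis uses them.

What the generator does **not** emulate: behavioural confounds (seasonality,
novelty effects after buying a new device), correlated missingness, workout
sessions, or realistic bpm values (bpm is carried as metadata only).  A
green recovery test therefore establishes that the pipeline estimates what
the design identifies, not that the design is immune to confounding in real
cohorts.

The worked toy fixture is a separate, fully hand-designed 4-participant
table (no randomness): one clean transition with an exact 50/50 tie day and
four hand-checkable wear days (40.0-min gap, 39.9-min gap, midnight-split
overnight gap, exact-600 wear day), one device alternator, one
version-jumper, and one double-upgrader with a hardware swap — arranged so
that each of the six exclusion reasons fires exactly once and exactly one
event is eligible.  Its outcome patterns are cyclic with tied maxima so the
percentile filter removes nothing.

## Numerical and degenerate-input choices

* Quantile definition: linear interpolation (NumPy default), fixed because
  implementations differ.
* Strict-majority scan: if a mode change never reaches a strict majority
  before the mode moves on (sub-daily flapping), no event is emitted.
* Empty panels, empty strata and non-converged fits are reported (logged,
  flagged) rather than fatal; all-zero outcomes are an error.
* Duplicate heart-rate rows are dropped only on exact match; conflicting
  duplicate activity rows are a hard error.
* Timestamps are timezone-naive local instants: days are defined by the
  wearer's local calendar date.

## Known limitations

* Effects of specific hardware generations are not estimable (pooled
  hardware events only), and joint software+hardware upgrades are excluded
  by design rather than modelled.
* Wald CIs can undercover slightly in small sex strata; no small-sample
  correction is applied.
* The generator's adoption process is independent across participants;
  real upgrade waves are more synchronized, which the control window —
  not the generator — is meant to address.
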