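import numpy as np
import pandas as pd
import pytest

import watchdrift as wd
from watchdrift.simulate import GeneratorConfig, lognormal_sigma


class TestConfigValidation:
    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            GeneratorConfig(n_participants=0)

    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="p_missing_day"):
            GeneratorConfig(p_missing_day=1.5)

    def test_nonpositive_effect_rejected(self):
        bad = {"exercise_minutes": {"8": -1.0}, "active_calories": {}}
        with pytest.raises(ValueError, match="effect"):
            GeneratorConfig(effects=bad)


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = dict(n_participants=5, seed=99, end_date="2020-12-31")
        a = wd.generate_cohort(GeneratorConfig(**cfg))
        b = wd.generate_cohort(GeneratorConfig(**cfg))
        pd.testing.assert_frame_equal(a.heart_rate, b.heart_rate)
        pd.testing.assert_frame_equal(a.activity, b.activity)
        assert a.ground_truth == b.ground_truth

    def test_different_seed_differs(self):
        a = wd.generate_cohort(GeneratorConfig(n_participants=5, seed=1, end_date="2020-12-31"))
        b = wd.generate_cohort(GeneratorConfig(n_participants=5, seed=2, end_date="2020-12-31"))
        assert not a.activity["exercise_minutes"].equals(b.activity["exercise_minutes"])


class TestOutcomeModel:
    def test_null_config_recovers_baseline_mean(self):
        """With no effects, flat weekdays and sigma_b = 0 the empirical mean
        matches the configured baseline (law of large numbers, >= 1e5 days)."""
        null_eff = {o: {} for o in ("exercise_minutes", "active_calories")}
        cfg = GeneratorConfig(
            n_participants=80,
            seed=4,
            start_date="2019-01-01",
            end_date="2022-12-31",
            effects=null_eff,
            sigma_b={"exercise_minutes": 0.0, "active_calories": 0.0},
            weekday_multipliers=tuple([1.0] * 7),
            p_missing_day=0.0,
            proportion_male=1.0,
        )
        cohort = wd.generate_cohort(cfg)
        assert len(cohort.activity) >= 1e5
        male_mean = cfg.baselines["exercise_minutes"]["male"][0]
        assert cohort.activity["exercise_minutes"].mean() == pytest.approx(male_mean, rel=0.02)

    def test_nb2_variance_structure(self):
        """Within one participant-weekday cell, Var(y) ~ mu + alpha mu^2."""
        null_eff = {o: {} for o in ("exercise_minutes", "active_calories")}
        alpha = 0.3
        cfg = GeneratorConfig(
            n_participants=1,
            seed=8,
            end_date="2022-12-31",
            effects=null_eff,
            sigma_b={"exercise_minutes": 0.0, "active_calories": 0.0},
            weekday_multipliers=tuple([1.0] * 7),
            alpha={"exercise_minutes": alpha, "active_calories": 0.05},
            p_missing_day=0.0,
        )
        y = wd.generate_cohort(cfg).activity["exercise_minutes"]
        mu = y.mean()
        assert y.var() == pytest.approx(mu + alpha * mu**2, rel=0.15)

    def test_upgrade_dates_monotone_per_participant(self):
        cohort = wd.generate_cohort(GeneratorConfig(n_participants=40, seed=13))
        ups = pd.DataFrame(cohort.ground_truth["upgrades"])
        sw = ups[ups["kind"] == "software"].dropna(subset=["transition_date"])
        for _, sub in sw.groupby("participant_id"):
            sub = sub.sort_values("transition_date")
            versions = sub["to_version"].astype(int).to_numpy()
            assert (np.diff(versions) > 0).all()

    def test_effects_switch_at_transition_date(self):
        """A large planted effect shows up after, not before, the ledger date."""
        eff = {"exercise_minutes": {"8": 2.0}, "active_calories": {}}
        cfg = GeneratorConfig(
            n_participants=25,
            seed=17,
            start_date="2021-06-01",
            end_date="2021-12-31",
            effects=eff,
            p_adopt_software=1.0,
            p_adopt_hardware=0.0,
            p_alternator=0.0,
            p_missing_day=0.0,
            weekday_multipliers=tuple([1.0] * 7),
        )
        cohort = wd.generate_cohort(cfg)
        ups = [u for u in cohort.ground_truth["upgrades"] if u["to_version"] == "8"]
        assert ups
        ratios = []
        act = cohort.activity.set_index(["participant_id", "date"])["exercise_minutes"]
        for u in ups:
            t = pd.Timestamp(u["transition_date"])
            pre = [act.get((u["participant_id"], t + pd.Timedelta(days=d))) for d in range(-7, 0)]
            post = [act.get((u["participant_id"], t + pd.Timedelta(days=d))) for d in range(0, 7)]
            ratios.append(np.nanmean(post) / np.nanmean(pre))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)


class TestSimulatePanel:
    def test_shape_and_labels(self):
        p = wd.simulate_panel(10, true_rr=1.1, seed=0)
        assert len(p) == 140
        assert set(p["post"]) == {0, 1}
        assert (p.groupby("participant_id")["date"].count() == 14).all()

    def test_control_window_has_no_effect(self):
        rng = np.random.default_rng(0)
        big = [
            wd.simulate_panel(300, true_rr=2.0, window_type="control", rng=rng)
            for _ in range(3)
        ]
        means = [
            p.groupby("post")["exercise_minutes"].mean() for p in big
        ]
        ratios = [m[1] / m[0] for m in means]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_lognormal_moment_match(self):
        assert lognormal_sigma(48.97, 34.05) == pytest.approx(
            np.sqrt(np.log(1 + (34.05 / 48.97) ** 2))
        )


class TestWorkedToy:
    def test_exactly_one_eligible_event(self, toy, toy_pipeline):
        events = toy_pipeline["events"]
        eligible = [e for e in events if e.eligible]
        assert len(eligible) == toy.expected_eligible_events == 1
        assert eligible[0].participant_id == "anna"
        assert eligible[0].transition_date == toy.expected_transition_date

    def test_wear_table_matches_hand_computation(self, toy, toy_pipeline):
        got = toy_pipeline["wear"].merge(
            toy.expected_wear[["participant_id", "date"]], on=["participant_id", "date"]
        )
        pd.testing.assert_frame_equal(
            got.reset_index(drop=True),
            toy.expected_wear.reset_index(drop=True),
            check_like=True,
        )

    def test_percentile_filter_removes_nothing(self, toy_pipeline):
        assert len(toy_pipeline["exclusions"]) == 0
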