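"""Tests for the staircase, task simulator and population generator."""

import math

import numpy as np
import pandas as pd
import pytest

from metaconf.sdt import VariantParams
from metaconf.simulate import (
    LOG_STRENGTH_BOUNDS,
    CalibrationConfig,
    ObserverSpec,
    PopulationConfig,
    StaircaseState,
    StimulusSpec,
    generate_population,
    population_profiles,
    population_trials,
    psychometric_theta,
    read_dataset,
    run_calibration,
    simulate_subject,
    simulate_task1,
    simulate_task2,
    staircase_step,
    write_dataset,
)


class TestStaircase:
    def test_two_down_rule(self):
        s = StaircaseState(log_strength=2.0, consecutive_correct=1, step_size=0.1)
        s2 = staircase_step(s, True)
        assert s2.log_strength == pytest.approx(1.9)
        assert s2.consecutive_correct == 0

    def test_first_correct_only_arms_counter(self):
        s = StaircaseState(log_strength=2.0, consecutive_correct=0)
        s2 = staircase_step(s, True)
        assert s2.log_strength == pytest.approx(2.0)
        assert s2.consecutive_correct == 1

    def test_one_up_rule_on_error(self):
        for armed in (0, 1):
            s = StaircaseState(log_strength=2.0, consecutive_correct=armed, step_size=0.1)
            s2 = staircase_step(s, False)
            assert s2.log_strength == pytest.approx(2.1)
            assert s2.consecutive_correct == 0

    def test_bounds_are_enforced(self):
        lo, hi = LOG_STRENGTH_BOUNDS
        s = StaircaseState(log_strength=hi, consecutive_correct=0)
        assert staircase_step(s, False).log_strength == hi
        s = StaircaseState(log_strength=lo, consecutive_correct=1)
        assert staircase_step(s, True).log_strength == lo

    def test_long_run_accuracy_near_707(self, rng):
        """At convergence a 2-down-1-up staircase holds the observer near the
        sqrt(0.5) ~ 70.7% accuracy level."""
        obs = ObserverSpec(miss_probability=0.0)
        state = StaircaseState(log_strength=3.8, step_size=0.1)
        correct_trials = []
        for _ in range(3000):
            d = int(rng.choice((-1, 1)))
            theta = psychometric_theta(state.log_strength, obs)
            x = d * theta + rng.standard_normal()
            correct = (1 if x > 0 else -1) == d
            correct_trials.append(correct)
            state = staircase_step(state, correct)
        assert np.mean(correct_trials[500:]) == pytest.approx(math.sqrt(0.5), abs=0.02)


class TestCalibration:
    def test_trial_counts_and_schema(self, rng):
        cal = run_calibration(ObserverSpec(), rng=rng)
        assert len(cal.trials) == 120
        assert (cal.trials.phase == "calibration").all()
        assert cal.trials.calib_high.sum() == 50
        assert cal.high_log_strength == pytest.approx(1.3 * cal.low_log_strength)

    def test_omniscient_observer_drives_strength_down(self, rng):
        # enormous gain: essentially always correct, strength falls monotonically
        obs = ObserverSpec(k=50.0)
        cal = run_calibration(obs, rng=rng)
        stair = cal.trials[cal.trials.calib_high == 0].log_strength_pre.to_numpy()
        assert cal.low_log_strength < 1.5
        assert (np.diff(stair) <= 1e-12).all()

    def test_blind_observer_strength_rises(self, rng):
        obs = ObserverSpec(k=1e-9)
        cal = run_calibration(obs, rng=rng)
        assert cal.low_log_strength > math.log(70)

    def test_pinned_staircase_warns(self, rng):
        # a long staircase for a chance-level observer parks at the upper
        # stimulus bound and triggers the diagnostic warning
        config = CalibrationConfig(n_staircase=400, n_high=0, burn_in=0)
        with pytest.warns(RuntimeWarning):
            run_calibration(ObserverSpec(k=1e-9), config=config, rng=rng)

    def test_default_observer_converges_near_71_percent(self):
        """Mean expected accuracy at the converged strength across observers
        is close to the ~71% the 2-down-1-up procedure targets."""
        from scipy.stats import norm

        accs = []
        for i in range(1, 41):
            obs = ObserverSpec()
            cal = run_calibration(obs, rng=np.random.default_rng(i))
            accs.append(norm.cdf(psychometric_theta(cal.low_log_strength, obs)))
        assert np.mean(accs) == pytest.approx(0.71, abs=0.02)


class TestPsychometric:
    def test_linear_gamma_preserves_ratio(self):
        obs = ObserverSpec(k=0.1, gamma=1.0)
        assert psychometric_theta(1.3 * 2.0, obs) / psychometric_theta(2.0, obs) == pytest.approx(1.3)

    def test_gain_is_proportional(self):
        lo = psychometric_theta(2.5, ObserverSpec(k=0.1))
        hi = psychometric_theta(2.5, ObserverSpec(k=0.2))
        assert hi == pytest.approx(2 * lo)

    def test_high_strength_performance_near_80_percent(self):
        """With the default exponent, the 1.3x log-strength manipulation lands
        near 80% expected accuracy for calibrated observers."""
        from scipy.stats import norm

        accs = []
        for i in range(1, 41):
            obs = ObserverSpec()
            cal = run_calibration(obs, rng=np.random.default_rng(i))
            accs.append(norm.cdf(psychometric_theta(cal.high_log_strength, obs)))
        assert np.mean(accs) == pytest.approx(0.80, abs=0.03)

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError):
            psychometric_theta(0.0, ObserverSpec())


class TestTasks:
    def test_task1_contract(self, rng):
        t1 = simulate_task1(ObserverSpec(miss_probability=0.0), 3.8, rng)
        assert len(t1) == 60
        assert (t1.post_level == "none").all()
        assert t1.missed.sum() == 0
        assert np.isin(t1.confidence.to_numpy(), np.linspace(0, 1, 9)).all()
        assert ((t1.choice == t1.d) == (t1.accuracy == 1)).all()
        assert abs(t1.d.sum()) <= 1  # balanced sides

    def test_task2_contract(self, rng):
        t2 = simulate_task2(ObserverSpec(miss_probability=0.0), 3.8, 4.94, rng)
        assert len(t2) == 120
        assert (t2.post_level.value_counts() == pd.Series({"low": 60, "high": 60})).all()
        # constrained interleaving: no more than 4 consecutive same level
        levels = t2.post_level.to_numpy()
        run, longest = 1, 1
        for i in range(1, len(levels)):
            run = run + 1 if levels[i] == levels[i - 1] else 1
            longest = max(longest, run)
        assert longest <= 4

    def test_task2_confidence_ordering_by_post_level(self):
        """For a base observer, confirmatory (correct) trials gain confidence
        with stronger post-decision evidence and errors lose it."""
        frames = [
            simulate_task2(ObserverSpec(miss_probability=0.0), 3.8, 4.94,
                           np.random.default_rng(seed), n_trials=600)
            for seed in range(5)
        ]
        t2 = pd.concat(frames)
        correct = t2[t2.accuracy == 1].groupby("post_level").confidence.mean()
        wrong = t2[t2.accuracy == 0].groupby("post_level").confidence.mean()
        assert correct["high"] > correct["low"]
        assert wrong["high"] < wrong["low"]

    def test_wbias_half_reduces_to_base(self):
        obs_bias = ObserverSpec(
            miss_probability=0.0, variant_params=VariantParams.choice_bias(0.5)
        )
        obs_base = ObserverSpec(miss_probability=0.0)
        t_bias = simulate_task1(obs_bias, 3.8, np.random.default_rng(9), n_trials=4000)
        t_base = simulate_task1(obs_base, 3.8, np.random.default_rng(9), n_trials=4000)
        assert t_bias.confidence.mean() == pytest.approx(t_base.confidence.mean(), abs=1e-12)

    def test_missed_trials_blank_choice_and_confidence(self, rng):
        t1 = simulate_task1(ObserverSpec(miss_probability=0.3), 3.8, rng, n_trials=400)
        missed = t1[t1.missed == 1]
        assert len(missed) > 50
        assert missed.choice.isna().all()
        assert missed.confidence.isna().all()

    def test_subject_session_trial_counts(self, rng):
        _, trials = simulate_subject(ObserverSpec(), rng)
        counts = trials.phase.value_counts()
        assert counts["calibration"] == 120
        assert counts["task1"] == 60
        assert counts["task2"] == 120


class TestPopulation:
    def test_determinism_under_seed(self):
        cfg = PopulationConfig(n_subjects=3)
        a = population_trials(generate_population(cfg, np.random.default_rng(5)))
        b = population_trials(generate_population(cfg, np.random.default_rng(5)))
        pd.testing.assert_frame_equal(a, b)

    def test_planted_factor_structure_recovered(self):
        """With default coefficients, regressions on the generated factor
        scores recover the planted quadratic/linear/correlation structure."""
        cfg = PopulationConfig(n_subjects=400, n_task1=0, n_task2=0,
                               calibration=CalibrationConfig(n_staircase=2, n_high=0,
                                                             burn_in=0, last_n=2))
        subjects = generate_population(cfg, np.random.default_rng(2))
        prof = population_profiles(subjects)
        zo = (prof.political_orientation - prof.political_orientation.mean()) / prof.political_orientation.std(ddof=0)
        zq = (zo**2 - (zo**2).mean()) / (zo**2).std(ddof=0)
        beta_quad = np.polyfit(zq, (prof.dogmatic_intolerance - prof.dogmatic_intolerance.mean()) / prof.dogmatic_intolerance.std(ddof=0), 1)[0]
        beta_lin = np.corrcoef(zo, prof.authoritarianism)[0, 1]
        corr_da = np.corrcoef(prof.dogmatic_intolerance, prof.authoritarianism)[0, 1]
        assert beta_quad == pytest.approx(0.37, abs=0.1)
        assert beta_lin == pytest.approx(0.38, abs=0.1)
        assert corr_da == pytest.approx(0.21, abs=0.12)

    def test_zero_coupling_gives_null_structure(self):
        cfg = PopulationConfig(n_subjects=600, quad_coef=0.0, lin_coef=0.0,
                               factor_corr=0.0, wbias_coupling=0.0,
                               n_task1=0, n_task2=0,
                               calibration=CalibrationConfig(n_staircase=2, n_high=0,
                                                             burn_in=0, last_n=2))
        subjects = generate_population(cfg, np.random.default_rng(3))
        prof = population_profiles(subjects)
        zo = (prof.political_orientation - prof.political_orientation.mean()) / prof.political_orientation.std(ddof=0)
        zq = zo**2 - (zo**2).mean()
        beta_quad = np.polyfit(zq / zq.std(ddof=0), prof.dogmatic_intolerance, 1)[0]
        assert abs(beta_quad) < 0.13
        wb = np.array([s.observer.variant_params.w_bias for s in subjects])
        comp = prof.composite_radicalism.to_numpy(float)
        assert abs(np.corrcoef(np.log(wb / (1 - wb)), comp)[0, 1]) < 0.15

    def test_wbias_coupling_planted(self):
        cfg = PopulationConfig(n_subjects=400, n_task1=0, n_task2=0,
                               calibration=CalibrationConfig(n_staircase=2, n_high=0,
                                                             burn_in=0, last_n=2))
        subjects = generate_population(cfg, np.random.default_rng(4))
        prof = population_profiles(subjects)
        wb = np.array([s.observer.variant_params.w_bias for s in subjects])
        r = np.corrcoef(np.log(wb / (1 - wb)), prof.composite_radicalism)[0, 1]
        assert r == pytest.approx(0.18, abs=0.1)

    def test_post_evidence_always_favors_true_side(self, rng):
        # contract is structural: the physical post strength is +theta on side d
        t2 = simulate_task2(ObserverSpec(miss_probability=0.0), 3.8, 4.94, rng)
        assert set(t2.post_level) == {"low", "high"}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_subjects=1)
        with pytest.raises(ValueError):
            PopulationConfig(n_subjects=5, wbias_coupling=float("nan"))


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        cfg = PopulationConfig(n_subjects=3)
        subjects = generate_population(cfg, np.random.default_rng(7))
        write_dataset(subjects, tmp_path / "ds")
        data = read_dataset(tmp_path / "ds")
        pd.testing.assert_frame_equal(
            data.trials, population_trials(subjects), check_dtype=False
        )
        ratings = data.trials.confidence.dropna().to_numpy()
        assert np.isin(ratings, np.linspace(0, 1, 9)).all()
        assert set(data.ground_truth) == {s.subject_id for s in subjects}

    def test_missing_column_is_named(self, tmp_path):
        cfg = PopulationConfig(n_subjects=2)
        subjects = generate_population(cfg, np.random.default_rng(8))
        write_dataset(subjects, tmp_path / "ds")
        trials = pd.read_csv(tmp_path / "ds" / "trials.csv").drop(columns=["post_level"])
        trials.to_csv(tmp_path / "ds" / "trials.csv", index=False)
        with pytest.raises(ValueError, match="post_level"):
            read_dataset(tmp_path / "ds")

    def test_unknown_phase_rejected(self, tmp_path):
        cfg = PopulationConfig(n_subjects=2)
        subjects = generate_population(cfg, np.random.default_rng(8))
        write_dataset(subjects, tmp_path / "ds")
        trials = pd.read_csv(tmp_path / "ds" / "trials.csv")
        trials.loc[0, "phase"] = "warmup"
        trials.to_csv(tmp_path / "ds" / "trials.csv", index=False)
        with pytest.raises(ValueError, match="phase"):
            read_dataset(tmp_path / "ds")


def test_stimulus_spec_bounds():
    with pytest.raises(ValueError):
        StimulusSpec(dot_difference=0, d=1)
    with pytest.raises(ValueError):
        StimulusSpec(dot_difference=400, d=1)
    s = StimulusSpec(dot_difference=70, d=-1)
    assert s.log_dot_difference == pytest.approx(math.log(70))
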