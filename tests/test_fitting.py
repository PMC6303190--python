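"""Tests for the quadrature likelihood and MAP fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from metaconf.fitting import (
    ConfidenceModel,
    PriorSpec,
    QuadratureConfig,
    fit_population,
    fits_frame,
    outcome_probabilities,
    posterior_predictive,
    trial_loglik,
)
from metaconf.sdt import (
    EvidenceStrengthPair,
    SubjectModelParams,
    VariantParams,
    confidence_from_logodds,
    decide,
    lo_correct_total,
    mixture_moments,
    simulate_report,
    single_moments,
)
from metaconf.simulate import ObserverSpec, simulate_subject

QUAD = QuadratureConfig(21, 15)


def make_params(variant=None, m=0.1, strengths=(0.6, 1.1), sigma_report=0.1):
    return SubjectModelParams(
        m=m, strengths=EvidenceStrengthPair(*strengths), sigma_report=sigma_report,
        variant_params=variant or VariantParams.base(),
    )


def mc_outcome_table(params, d, post_level, n, rng):
    """Monte-Carlo frequencies of (choice, snapped rating) outcomes."""
    dd = np.full(n, d)
    x_pre = dd * params.strengths.mu_low + rng.standard_normal(n)
    actions = np.asarray(decide(x_pre, params.m, rng=rng))
    if post_level == "none":
        moments = single_moments(params.strengths.mu_low)
        x_post = None
    else:
        moments = mixture_moments(params.strengths)
        theta = params.strengths.theta_post(post_level)
        x_post = dd * theta + rng.standard_normal(n)
    conf = np.empty(n)
    for a in (-1, 1):
        mask = actions == a
        xp = None if x_post is None else x_post[mask]
        conf[mask] = confidence_from_logodds(
            lo_correct_total(x_pre[mask], xp, a, params, moments)
        )
    ratings = simulate_report(conf, params.sigma_report, rng)
    table = np.zeros((2, 9))
    for i, a in enumerate((-1, 1)):
        for k in range(9):
            table[i, k] = np.mean((actions == a) & (np.abs(ratings - k / 8) < 1e-9))
    return table


class TestLikelihoodOracle:
    def test_outcome_probabilities_normalize(self):
        for variant in (VariantParams.base(), VariantParams.choice_bias(0.7),
                        VariantParams.temporal(0.8, 1.3), VariantParams.choice_weighting(1.2, 0.4)):
            params = make_params(variant)
            for level in ("none", "low", "high"):
                tab = outcome_probabilities(params, d=1, post_level=level, quadrature=QUAD)
                assert tab.sum() == pytest.approx(1.0, abs=1e-6)

    def test_quadrature_matches_monte_carlo_spot_checks(self):
        """Quadrature outcome probabilities agree with simulation frequencies
        within 0.01 per (choice x rating) bin (short sweep; the full 20-point
        sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(2024)
        n = 100_000
        worst = 0.0
        for _ in range(5):
            mu_low = rng.uniform(0.3, 1.0)
            params = make_params(
                variant=VariantParams.choice_bias(rng.uniform(0.35, 0.75)),
                m=rng.uniform(-0.4, 0.4),
                strengths=(mu_low, mu_low + rng.uniform(0.0, 0.8)),
                sigma_report=rng.uniform(0.05, 0.2),
            )
            d = int(rng.choice((-1, 1)))
            level = str(rng.choice(("none", "low", "high")))
            quad_tab = outcome_probabilities(params, d, level, quadrature=QuadratureConfig(61, 41))
            mc_tab = mc_outcome_table(params, d, level, n, rng)
            worst = max(worst, float(np.abs(quad_tab - mc_tab).max()))
        assert worst < 0.01

    def test_trial_loglik_consistency(self):
        params = make_params(VariantParams.choice_bias(0.6))
        tab = outcome_probabilities(params, 1, "low", quadrature=QUAD)
        ll = trial_loglik(params, (1, "low", 1, 0.875), quadrature=QUAD, rating_mode="binned")
        assert ll == pytest.approx(math.log(tab[1, 7]), abs=1e-9)

    def test_variant_reduction_identical_loglik(self):
        base = make_params()
        bias_half = make_params(VariantParams.choice_bias(0.5))
        for obs in [(1, "none", 1, 0.75), (-1, "high", -1, 0.5), (1, "low", -1, 0.25)]:
            assert trial_loglik(base, obs, quadrature=QUAD) == pytest.approx(
                trial_loglik(bias_half, obs, quadrature=QUAD), abs=1e-9
            )

    def test_invalid_observation_rejected(self):
        params = make_params()
        with pytest.raises(ValueError):
            trial_loglik(params, (1, "none", 0, 0.5))
        with pytest.raises(ValueError):
            trial_loglik(params, (1, "none", 1, 0.3))  # off the grid

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            QuadratureConfig(n_pre=5, n_post=41)


class TestSubjectFit:
    def test_recovers_wbias_large_sample(self):
        """A 10k-trial synthetic choice-bias subject is recovered within
        +-0.05 on w_bias."""
        obs = ObserverSpec(m=0.0, variant_params=VariantParams.choice_bias(0.6),
                           miss_probability=0.0)
        _, trials = simulate_subject(obs, np.random.default_rng(5),
                                     n_task1=3000, n_task2=7000)
        res = ConfidenceModel(trials, "choice_bias", quadrature=QUAD).fit(n_starts=2)
        assert res.converged
        assert abs(res.params["w_bias"] - 0.6) < 0.05

    def test_base_generated_data_yields_neutral_bias(self):
        _, trials = simulate_subject(
            ObserverSpec(m=0.0, miss_probability=0.0), np.random.default_rng(6),
            n_task1=3000, n_task2=7000,
        )
        res = ConfidenceModel(trials, "choice_bias", quadrature=QUAD).fit(n_starts=2)
        assert abs(res.params["w_bias"] - 0.5) < 0.05

    def test_empty_dataset_rejected(self):
        empty = pd.DataFrame(columns=["phase", "d", "post_level", "choice",
                                      "confidence", "missed", "subject_id"])
        with pytest.raises(ValueError):
            ConfidenceModel(empty, "choice_bias")

    def test_results_surface(self, choice_bias_subject):
        _, _, trials = choice_bias_subject
        res = ConfidenceModel(trials, "choice_bias", quadrature=QUAD,
                              sigma_report=0.1).fit(n_starts=1)
        text = res.summary()
        assert "w_bias" in text and "log joint" in text
        assert len(res.bse) == len(res.model.param_names)
        assert np.isfinite(res.llf)
        fr = res.to_fit_result()
        assert fr.variant == "choice_bias"
        sim = res.simulate(200, np.random.default_rng(0))
        assert set(sim.condition) == {"task1", "task2_low", "task2_high"}

    def test_seeded_fit_reproducible(self, choice_bias_subject):
        _, _, trials = choice_bias_subject
        a = ConfidenceModel(trials, "choice_bias", quadrature=QUAD).fit(n_starts=3, seed=9)
        b = ConfidenceModel(trials, "choice_bias", quadrature=QUAD).fit(n_starts=3, seed=9)
        assert np.allclose(a.params_vector, b.params_vector)


class TestPopulationFit:
    @staticmethod
    def homogeneous_tables(n, seed0):
        tables = []
        for i in range(n):
            obs = ObserverSpec(m=0.15, miss_probability=0.0)
            _, t = simulate_subject(obs, np.random.default_rng(seed0 + i))
            tables.append(t)
        return tables

    def test_hierarchical_shrinkage(self):
        """Empirical-Bayes updating of the group priors shrinks the spread of
        per-subject criterion estimates for homogeneous subjects."""
        tables = self.homogeneous_tables(8, 900)
        quad = QuadratureConfig(13, 9)
        independent = fit_population(tables, "base", quadrature=quad,
                                     hierarchical=False, n_starts=1)
        hierarchical = fit_population(tables, "base", quadrature=quad,
                                      hierarchical=True, n_starts=1, max_em_iter=2)
        sd_ind = np.std([r.params["m"] for r in independent])
        sd_hier = np.std([r.params["m"] for r in hierarchical])
        assert sd_hier <= sd_ind + 1e-9

    def test_single_subject_hierarchical_warns(self):
        tables = self.homogeneous_tables(1, 950)
        with pytest.warns(RuntimeWarning):
            res = fit_population(tables, "base", quadrature=QuadratureConfig(13, 9),
                                 hierarchical=True, n_starts=1)
        assert len(res) == 1

    def test_fits_frame_layout(self):
        tables = self.homogeneous_tables(2, 960)
        res = fit_population(tables, "choice_bias", quadrature=QuadratureConfig(13, 9),
                             n_starts=1)
        frame = fits_frame(res)
        assert {"mu_low", "mu_high", "w_bias", "llf"} <= set(frame.columns)
        assert len(frame) == 2


class TestPosteriorPredictive:
    def test_decile_split_and_cells(self):
        tables = TestPopulationFit.homogeneous_tables(5, 970)
        res = fit_population(tables, "choice_bias", quadrature=QuadratureConfig(13, 9),
                             n_starts=1)
        # distinct subject ids
        for i, r in enumerate(res):
            r.model.subject_id = f"s{i}"
        comp = pd.Series(np.linspace(-1, 1, 5), index=[f"s{i}" for i in range(5)])
        table = posterior_predictive(res, comp, n_draws=1, n_trials=400,
                                     rng=np.random.default_rng(3))
        assert set(table.group) == {"radical", "moderate"}
        assert (table[table.group == "radical"].n_subjects == 1).all()
        assert set(table.condition) == {"task1", "task2_low", "task2_high"}

    def test_point_prediction_tracks_generating_cells(self, base_subject):
        """Simulating from a good fit reproduces the generating data's mean
        confidence per condition x accuracy cell."""
        _, _, trials = base_subject
        res = ConfidenceModel(trials, "base", quadrature=QUAD).fit(n_starts=1)
        sim = res.simulate(20_000, np.random.default_rng(8))
        tasks = trials[trials.phase.isin(("task1", "task2"))]
        obs_t1 = tasks[tasks.phase == "task1"].confidence.mean()
        sim_t1 = sim[sim.condition == "task1"].confidence.mean()
        assert sim_t1 == pytest.approx(obs_t1, abs=0.06)

    def test_invalid_sizes_rejected(self, base_subject):
        _, _, trials = base_subject
        res = ConfidenceModel(trials, "base", quadrature=QUAD).fit(n_starts=1)
        with pytest.raises(ValueError):
            posterior_predictive([res], pd.Series({res.model.subject_id: 0.0}), n_draws=0)
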