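"""Least-squares fitting, BIC, model comparison and rating preprocessing."""

import math

import numpy as np
import pytest

from hedonometer import (
    CANONICAL_MODELS,
    FitResult,
    HappinessParams,
    ModelSpec,
    RatingSeries,
    build_regressors,
    compare_models,
    compute_bic,
    fit_model,
    likelihood_ratio_test,
    standardize_ratings,
    trim_and_detrend,
)
from hedonometer.fitting import profile_rss
from hedonometer.model import decayed_series


def grid_search_oracle(spec, regressors, y):
    """Independent oracle: dense gamma grid with an explicit linear solve."""
    at = regressors.probe_trials - 1
    best = np.inf
    for g in np.linspace(0.0, 1.0, 101):
        cols = []
        if spec.include_baseline:
            cols.append(np.ones(at.size))
        for term in spec.terms:
            cols.append(decayed_series(regressors.column(term), g)[at])
        X = np.column_stack(cols)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        best = min(best, rss)
    return best


class TestFit:
    def test_noise_free_parameters_recovered(self, noiseless_session, rp_model):
        trials, ratings, true = noiseless_session
        regs = build_regressors(trials, ratings)
        fit = fit_model(ratings, regs, rp_model)
        assert fit.params.w_reward == pytest.approx(true.w_reward, abs=1e-4)
        assert fit.params.w_performance == pytest.approx(true.w_performance, abs=1e-4)
        assert fit.params.gamma == pytest.approx(true.gamma, abs=1e-4)
        assert fit.rss < 1e-12
        assert fit.r_squared > 1 - 1e-10

    def test_weights_match_closed_form_at_fitted_gamma(self, session, rp_model):
        trials, ratings = session
        regs = build_regressors(trials, ratings)
        fit = fit_model(ratings, regs, rp_model)
        _, coef = profile_rss(rp_model, regs, ratings.rating, np.array([fit.params.gamma]))
        assert fit.params.w_reward == pytest.approx(coef[0], abs=1e-8)
        assert fit.params.w_performance == pytest.approx(coef[1], abs=1e-8)

    def test_optimizer_matches_gamma_grid_oracle(self, rp_model):
        """Profile optimizer RSS agrees with dense-grid + closed-form weights on 20 datasets."""
        from hedonometer import AgentSpec, TaskConfig, simulate_session

        for seed in range(20):
            trials, ratings = simulate_session(TaskConfig(), AgentSpec(), rng_seed=2000 + seed)
            regs = build_regressors(trials, ratings)
            fit = fit_model(ratings, regs, rp_model)
            oracle = grid_search_oracle(rp_model, regs, ratings.rating)
            assert fit.rss <= oracle + 1e-6

    def test_pure_noise_gives_small_weights_and_r2(self, rp_model):
        from hedonometer import AgentSpec, TaskConfig, simulate_session

        cfg = TaskConfig(n_trials=480, rng_seed=0)
        params = HappinessParams(w_reward=0.0, w_performance=0.0, gamma=0.5, sigma=1.0)
        trials, ratings = simulate_session(cfg, AgentSpec(happiness_params=params), rng_seed=9)
        regs = build_regressors(trials, ratings)
        fit = fit_model(ratings, regs, rp_model)
        assert abs(fit.params.w_reward) < 0.12
        assert abs(fit.params.w_performance) < 0.12
        assert fit.r_squared < 0.08

    def test_raw_mode_fit_recovers_baseline(self, session):
        trials, _ = session
        from hedonometer import generate_ratings

        spec = ModelSpec(terms=("reward",), include_baseline=True, rating_mode="raw")
        true = HappinessParams(w0=62.0, w_reward=4.0, gamma=0.4, sigma=0.0)
        ratings = generate_ratings(trials, true, spec, rng_seed=0)
        regs = build_regressors(trials, ratings)
        fit = fit_model(ratings, regs, spec)
        assert fit.params.w0 == pytest.approx(62.0, abs=1e-3)
        assert fit.params.w_reward == pytest.approx(4.0, abs=1e-3)

    def test_too_few_ratings_rejected(self, session, rp_model):
        trials, ratings = session
        short = RatingSeries(trial_index=ratings.trial_index[:6], rating=ratings.rating[:6])
        regs = build_regressors(trials, short)
        with pytest.raises(ValueError):
            fit_model(short, regs, rp_model)

    def test_sigma_is_mle_residual_sd(self, session, rp_model):
        trials, ratings = session
        regs = build_regressors(trials, ratings)
        fit = fit_model(ratings, regs, rp_model)
        assert fit.params.sigma == pytest.approx(math.sqrt(fit.rss / fit.n_ratings), abs=1e-12)


def make_fit(rss, n, k_terms=("reward", "performance")):
    spec = ModelSpec(terms=k_terms)
    f = FitResult(
        spec=spec,
        params=HappinessParams(),
        rss=rss,
        r_squared=0.0,
        n_ratings=n,
        bic=float("nan"),
        n_restarts_used=1,
        converged=True,
    )
    f.bic = compute_bic(f)
    return f


class TestBic:
    def test_hand_computed_value(self):
        f = make_fit(36.125, 50)  # k = 3
        assert f.bic == pytest.approx(50 * math.log(0.7225) + 3 * math.log(50), abs=1e-10)
        assert f.bic == pytest.approx(-4.52, abs=0.01)

    def test_equal_rss_larger_k_larger_bic(self):
        small = make_fit(10.0, 40, ("reward",))
        sep = FitResult(
            spec=ModelSpec(terms=("reward", "performance"), shared_gamma=False),
            params=HappinessParams(),
            rss=10.0,
            r_squared=0.0,
            n_ratings=40,
            bic=float("nan"),
            n_restarts_used=1,
            converged=True,
        )
        sep.bic = compute_bic(sep)
        assert sep.bic > small.bic

    def test_doubling_residuals_adds_2n_log2(self):
        f1 = make_fit(9.0, 30)
        f2 = make_fit(4 * 9.0, 30)  # doubling residuals quadruples RSS
        assert f2.bic - f1.bic == pytest.approx(2 * 30 * math.log(2), abs=1e-9)

    def test_zero_rss_guarded(self):
        with pytest.raises(ValueError):
            make_fit(0.0, 30)


class TestComparison:
    def test_lowest_bic_wins_with_zero_delta(self):
        fits = {"a_model": [make_fit(5.0, 40)], "b_model": [make_fit(9.0, 40)]}
        # reuse the reward spec for both; only BIC ordering matters here
        table = compare_models(fits).table
        assert table.loc["a_model", "delta_bic"] == 0.0
        assert table.loc["b_model", "delta_bic"] > 0.0

    def test_missing_subject_cells_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": [make_fit(5.0, 40)], "b": []})

    def test_bic_ordering_invariant_to_rating_shift_in_raw_mode(self, session):
        from hedonometer import generate_ratings

        trials, _ = session
        spec = ModelSpec(terms=("reward",), include_baseline=True, rating_mode="raw")
        true = HappinessParams(w0=55.0, w_reward=4.0, gamma=0.4, sigma=3.0)
        ratings = generate_ratings(trials, true, spec, rng_seed=4)
        regs = build_regressors(trials, ratings)
        shifted = RatingSeries(
            trial_index=ratings.trial_index, rating=ratings.rating + 10.0, mode="raw"
        )
        f1 = fit_model(ratings, regs, spec)
        f2 = fit_model(shifted, regs, spec)
        assert f2.bic == pytest.approx(f1.bic, abs=1e-5)  # w0 absorbs the shift
        assert f2.params.w0 == pytest.approx(f1.params.w0 + 10.0, abs=1e-5)


class TestPreprocessing:
    def _ratings(self, n):
        return RatingSeries(trial_index=np.arange(2, 2 + 2 * n, 2), rating=np.linspace(-1, 1, n))

    def test_trim_ceiling_arithmetic(self):
        out = trim_and_detrend(self._ratings(50), trim_fraction=0.10)
        assert out.n == 45

    def test_detrend_linear_series_leaves_zeros(self):
        out = trim_and_detrend(self._ratings(40), trim_fraction=0.0, detrend=True)
        np.testing.assert_allclose(out.rating, 0.0, atol=1e-12)

    def test_noop_is_identity(self):
        r = self._ratings(30)
        out = trim_and_detrend(r, trim_fraction=0.0, detrend=False)
        np.testing.assert_array_equal(out.rating, r.rating)
        np.testing.assert_array_equal(out.trial_index, r.trial_index)

    def test_overtrimming_rejected(self):
        with pytest.raises(ValueError):
            trim_and_detrend(self._ratings(10), trim_fraction=0.5)

    def test_standardize_ratings_r2_invariance_on_centered_data(self, session, rp_model):
        trials, ratings = session
        regs = build_regressors(trials, ratings)
        centered = RatingSeries(
            trial_index=ratings.trial_index, rating=ratings.rating - ratings.rating.mean()
        )
        f1 = fit_model(centered, regs, rp_model)
        f2 = fit_model(standardize_ratings(ratings), regs, rp_model)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-6)


class TestLikelihoodRatio:
    def test_nested_test_detects_true_performance_term(self, session):
        trials, ratings = session  # generated with w_performance = 0.18 > 0
        regs = build_regressors(trials, ratings)
        full = fit_model(ratings, regs, CANONICAL_MODELS["reward_performance"])
        reduced = fit_model(ratings, regs, CANONICAL_MODELS["reward"])
        stat, df, p = likelihood_ratio_test(full, reduced)
        assert stat >= 0 and df == 1
        assert 0.0 <= p <= 1.0

    def test_wrong_nesting_rejected(self, session):
        trials, ratings = session
        regs = build_regressors(trials, ratings)
        full = fit_model(ratings, regs, CANONICAL_MODELS["reward_performance"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, full)
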