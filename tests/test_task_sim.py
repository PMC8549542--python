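"""Task simulator: schedule structure, chooser behavior, rating generation."""

import numpy as np
import pytest
from scipy import stats as sps

from hedonometer import (
    AgentSpec,
    HappinessParams,
    ModelSpec,
    TaskConfig,
    build_regressors,
    generate_ratings,
    generate_schedule,
    predict_happiness,
    simulate_agent_choices,
    simulate_session,
)


class TestSchedule:
    def test_reversal_gaps_within_bounds(self):
        sch = generate_schedule(TaskConfig(n_trials=100, rng_seed=7))
        gaps = np.diff(np.concatenate([[0], sch.reversal_trials]))
        assert ((gaps >= 19) & (gaps <= 23)).all()

    def test_fixed_probe_gap_enumerates_every_other_trial(self):
        sch = generate_schedule(TaskConfig(n_trials=120, probe_min=2, probe_max=2, rng_seed=1))
        assert np.array_equal(sch.probe_trials, np.arange(2, 121, 2))

    def test_zero_free_fraction_means_all_forced(self):
        sch = generate_schedule(TaskConfig(free_choice_fraction=0.0, rng_seed=2))
        assert all(c == "forced" for c in sch.choice_types)
        assert all(opt in "AB" for opt in sch.forced_options)

    def test_free_fraction_matches_up_to_rounding(self):
        sch = generate_schedule(TaskConfig(n_trials=121, free_choice_fraction=0.5, rng_seed=3))
        assert sch.choice_types.count("free") == round(0.5 * 121)

    def test_forced_trials_split_high_low_equally(self):
        sch = generate_schedule(TaskConfig(rng_seed=4))
        forced = [
            (sch.forced_options[j] == sch.high_option[j])
            for j in range(sch.n_trials)
            if sch.choice_types[j] == "forced"
        ]
        assert abs(sum(forced) - len(forced) / 2) <= 0.5

    def test_high_option_flips_exactly_at_reversals(self):
        sch = generate_schedule(TaskConfig(rng_seed=5))
        flips = [j + 1 for j in range(1, sch.n_trials) if sch.high_option[j] != sch.high_option[j - 1]]
        assert flips == list(sch.reversal_trials)

    def test_reversal_gap_distribution_uniform(self):
        """Empirical inter-reversal gaps are uniform on {19..23} (chi-square, alpha=0.01)."""
        rng_seeds = range(4000)
        gaps = []
        for s in rng_seeds:
            sch = generate_schedule(TaskConfig(n_trials=120, rng_seed=s))
            gaps.extend(np.diff(np.concatenate([[0], sch.reversal_trials])))
        counts = np.bincount(gaps, minlength=24)[19:24]
        assert sps.chisquare(counts).pvalue > 0.01

    def test_deterministic_given_seed(self):
        a = generate_schedule(TaskConfig(rng_seed=9))
        b = generate_schedule(TaskConfig(rng_seed=9))
        assert np.array_equal(a.reversal_trials, b.reversal_trials)
        assert a.choice_types == b.choice_types
        assert np.array_equal(a.probe_trials, b.probe_trials)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trials": 10},  # below reversal_min: no reversal realizable
            {"reversal_min": 23, "reversal_max": 19},
            {"probe_min": 3, "probe_max": 2},
            {"free_choice_fraction": 1.5},
            {"n_barriers": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TaskConfig(**kwargs)


class TestChooser:
    def test_zero_inverse_temperature_is_random_policy(self):
        cfg = TaskConfig(rng_seed=0)
        agent = AgentSpec(inverse_temperature=0.0)
        rng = np.random.default_rng(0)
        correct = []
        for s in range(30):
            sch = generate_schedule(TaskConfig(rng_seed=s))
            chosen, _ = simulate_agent_choices(sch, agent, cfg, rng)
            correct += [c == h for c, h, t in zip(chosen, sch.high_option, sch.choice_types) if t == "free"]
        assert abs(np.mean(correct) - 0.5) < 0.03

    def test_zero_learning_rate_freezes_choice_probabilities(self):
        # equal initial values never update, so the policy stays uniform
        cfg = TaskConfig(rng_seed=0)
        agent = AgentSpec(learning_rate=0.0, inverse_temperature=5.0)
        rng = np.random.default_rng(1)
        a_choices = []
        for s in range(30):
            sch = generate_schedule(TaskConfig(rng_seed=100 + s))
            chosen, _ = simulate_agent_choices(sch, agent, cfg, rng)
            a_choices += [c == "A" for c, t in zip(chosen, sch.choice_types) if t == "free"]
        assert abs(np.mean(a_choices) - 0.5) < 0.03

    def test_delta_rule_learner_beats_chance(self):
        cfg = TaskConfig()
        agent = AgentSpec()
        accs = []
        for s in range(25):
            trials, _ = simulate_session(cfg, agent, rng_seed=s)
            accs.append(
                np.mean([t.chosen_option == t.high_option_identity for t in trials if t.choice_type == "free"])
            )
        assert np.mean(accs) > 0.75

    def test_reward_marginals_match_option_distributions(self):
        cfg = TaskConfig()
        agent = AgentSpec()
        high_pts, low_pts = [], []
        for s in range(80):
            trials, _ = simulate_session(cfg, agent, rng_seed=1000 + s)
            for t in trials:
                (high_pts if t.chosen_option == t.high_option_identity else low_pts).append(t.reward_points)
        assert np.mean(high_pts) == pytest.approx(50.0, abs=0.3)
        assert np.mean(low_pts) == pytest.approx(25.0, abs=0.3)
        assert np.std(high_pts) == pytest.approx(10.0, abs=0.3)
        assert np.std(low_pts) == pytest.approx(10.0, abs=0.3)


class TestRatings:
    def test_zero_noise_ratings_equal_model_predictions(self, noiseless_session, rp_model):
        trials, ratings, params = noiseless_session
        regs = build_regressors(trials, ratings)
        np.testing.assert_array_equal(ratings.rating, predict_happiness(rp_model, params, regs))

    def test_gamma_zero_rating_is_last_trial_reward(self, session):
        trials, _ = session
        params = HappinessParams(w_reward=1.0, w_performance=0.0, gamma=0.0, sigma=0.0)
        ratings = generate_ratings(trials, params, ModelSpec(), rng_seed=0)
        regs = build_regressors(trials)
        np.testing.assert_allclose(ratings.rating, regs.reward[regs.probe_trials - 1], rtol=0, atol=1e-15)

    def test_constant_baseline_in_raw_mode(self, session):
        trials, _ = session
        spec = ModelSpec(terms=("reward",), include_baseline=True, rating_mode="raw")
        params = HappinessParams(w0=62.0, w_reward=0.0, gamma=0.3, sigma=0.0)
        ratings = generate_ratings(trials, params, spec, rng_seed=0)
        assert (ratings.rating == 62.0).all()
        assert ratings.mode == "raw"

    def test_raw_ratings_clipped_to_scale_zscored_not(self, session):
        trials, _ = session
        raw_spec = ModelSpec(terms=("reward",), include_baseline=True, rating_mode="raw")
        params = HappinessParams(w0=95.0, w_reward=50.0, gamma=0.9, sigma=30.0)
        raw = generate_ratings(trials, params, raw_spec, rng_seed=5)
        assert raw.rating.min() >= 0.0 and raw.rating.max() <= 100.0
        z = generate_ratings(
            trials,
            HappinessParams(w_reward=50.0, w_performance=0.0, gamma=0.9, sigma=30.0),
            ModelSpec(),
            rng_seed=5,
        )
        assert z.rating.max() > 100.0 or z.rating.min() < 0.0

    def test_negative_sigma_rejected(self, session):
        trials, _ = session
        params = HappinessParams(w_reward=0.4, w_performance=0.2, gamma=0.5, sigma=-1.0)
        with pytest.raises(ValueError):
            generate_ratings(trials, params, ModelSpec())

    def test_session_determinism_identical_logs(self, task_config):
        agent = AgentSpec()
        t1, r1 = simulate_session(task_config, agent, rng_seed=21)
        t2, r2 = simulate_session(task_config, agent, rng_seed=21)
        assert [vars(a) for a in t1] == [vars(b) for b in t2]
        np.testing.assert_array_equal(r1.rating, r2.rating)
        np.testing.assert_array_equal(r1.trial_index, r2.trial_index)

    def test_rating_variance_decomposes_into_signal_plus_noise(self):
        """Generated standardized ratings have variance ~ signal variance + sigma^2."""
        cfg = TaskConfig()
        sigma = 0.85
        total, signal = [], []
        for s in range(33):
            params = HappinessParams(w_reward=0.39, w_performance=0.18, gamma=0.48, sigma=sigma)
            trials, ratings = simulate_session(cfg, AgentSpec(happiness_params=params), rng_seed=500 + s)
            regs = build_regressors(trials, ratings)
            pred = predict_happiness(ModelSpec(), params, regs)
            total.append(np.var(ratings.rating))
            signal.append(np.var(pred))
        assert np.mean(total) == pytest.approx(np.mean(signal) + sigma**2, abs=0.08)
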