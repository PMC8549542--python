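import numpy as np
import pytest

from hedonometer import (
    AgentSpec,
    CANONICAL_MODELS,
    HappinessParams,
    TaskConfig,
    build_regressors,
    simulate_session,
)


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig(rng_seed=7)


@pytest.fixture(scope="session")
def session(task_config):
    """One simulated subject: (trials, ratings) under the reward+performance model."""
    agent = AgentSpec()
    return simulate_session(task_config, agent, rng_seed=3)


@pytest.fixture(scope="session")
def regressors(session):
    trials, ratings = session
    return build_regressors(trials, ratings)


@pytest.fixture(scope="session")
def noiseless_session(task_config):
    """Deterministic-rating subject (sigma = 0) with known generative parameters."""
    params = HappinessParams(w_reward=0.4, w_performance=0.2, gamma=0.5, sigma=0.0)
    agent = AgentSpec(happiness_params=params)
    trials, ratings = simulate_session(task_config, agent, rng_seed=11)
    return trials, ratings, params


@pytest.fixture(scope="session")
def rp_model():
    return CANONICAL_MODELS["reward_performance"]
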