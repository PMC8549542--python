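"""Synthetic probabilistic-reversal task with a skilled-performance component.

Emulates a two-option reward-learning task in which one option pays ~50
points on average and the other ~25 (both SD 10), the high option reverses
every 19-23 trials, half the trials are free choices and half forced, every
trial ends with a staircased cursor run past four barriers (~70% barrier-free
success), and a happiness probe follows every 2-3 trials.  Happiness ratings
are generated from the discounted-history model in :mod:`hedonometer.model`
with Gaussian noise.

The simulated chooser is a delta-rule value learner with a softmax policy; it
exists only to produce plausible choice streams (the affective model does not
depend on how choices arise), with defaults calibrated so cohort accuracy to
the currently-high option lands in the mid-80% range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import HappinessParams, ModelSpec, build_regressors, predict_happiness
from .staircase import LogisticPerformer, StaircaseState, init_staircase, pest_update, run_calibration

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "AgentSpec",
    "RatingSeries",
    "Schedule",
    "generate_schedule",
    "simulate_agent_choices",
    "simulate_trial_outcomes",
    "generate_ratings",
    "simulate_session",
    "RATING_SCALE",
]

#: Raw rating line bounds and midpoint (cursor starts at the midpoint).
RATING_SCALE = (0.0, 100.0)


@dataclass(frozen=True)
class TaskConfig:
    """Task-structure configuration; defaults emulate the study design."""

    n_trials: int = 120
    n_blocks: int = 2
    reward_mean_high: float = 50.0
    reward_mean_low: float = 25.0
    reward_sd: float = 10.0
    reversal_min: int = 19
    reversal_max: int = 23
    free_choice_fraction: float = 0.5
    probe_min: int = 2
    probe_max: int = 3
    n_barriers: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trials", "n_blocks", "reversal_min", "reversal_max",
                     "probe_min", "probe_max", "n_barriers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.reversal_min > self.reversal_max:
            raise ValueError("reversal_min must not exceed reversal_max")
        if self.probe_min > self.probe_max:
            raise ValueError("probe_min must not exceed probe_max")
        if not 0.0 <= self.free_choice_fraction <= 1.0:
            raise ValueError("free_choice_fraction must lie in [0, 1]")
        if self.n_trials < self.reversal_min:
            raise ValueError(
                f"n_trials={self.n_trials} < reversal_min={self.reversal_min}: "
                "no reversal is realizable"
            )


@dataclass
class TrialRecord:
    """One completed task trial."""

    trial_index: int
    block: int
    choice_type: str  # {"free", "forced"}
    high_option_identity: str  # {"A", "B"}: which option is currently high-mean
    chosen_option: str  # {"A", "B"}
    reward_points: float
    collision: int  # 1 = contacted >= 1 barrier, 0 = clean run
    cursor_speed: float
    probe_after: int


@dataclass(frozen=True)
class AgentSpec:
    """Simulated agent: chooser, performer and affective model."""

    learning_rate: float = 0.7
    inverse_temperature: float = 0.5  # on the points scale
    psychometric_threshold: float = 1.0  # speed at 50% success
    psychometric_slope: float = 5.0  # logistic slope of success vs speed
    happiness_params: HappinessParams = field(
        default_factory=lambda: HappinessParams(
            w_reward=0.39, w_performance=0.18, gamma=0.48, sigma=0.85
        )
    )
    rating_noise_mode: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be non-negative")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be positive")
        if self.rating_noise_mode != "gaussian":
            raise ValueError("only gaussian rating noise is supported")

    @property
    def performer(self) -> LogisticPerformer:
        return LogisticPerformer(self.psychometric_threshold, self.psychometric_slope)


@dataclass
class RatingSeries:
    """Sparse happiness ratings aligned to probe trials.

    ``mode`` is ``"raw"`` (native 0-100 line) or ``"zscored"``.  An optional
    pre-task rating (before trial 1) is stored separately and excluded from
    fitting by default.
    """

    trial_index: np.ndarray
    rating: np.ndarray
    mode: str = "zscored"
    pre_task_rating: float | None = None

    def __post_init__(self) -> None:
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        self.rating = np.asarray(self.rating, dtype=float)
        if self.trial_index.shape != self.rating.shape:
            raise ValueError("trial_index and rating lengths differ")
        if self.mode not in ("raw", "zscored"):
            raise ValueError(f"invalid rating mode {self.mode!r}")

    @property
    def n(self) -> int:
        return int(self.rating.size)


@dataclass
class Schedule:
    """Pre-drawn trial structure: reversals, choice types, probes."""

    n_trials: int
    reversal_trials: np.ndarray  # 1-based trial indices at which the high option flips
    choice_types: list[str]  # per trial, "free" or "forced"
    forced_options: list[str]  # per trial: on forced trials, the single option shown
    probe_trials: np.ndarray  # 1-based trial indices followed by a probe
    high_option: list[str]  # per trial, which option is currently high-mean
    block: np.ndarray  # per trial block number (1-based)


def generate_schedule(config: TaskConfig) -> Schedule:
    """Draw the trial structure for one session.

    Inter-reversal gaps are uniform on {reversal_min..reversal_max}; the
    free/forced split matches ``free_choice_fraction`` up to rounding, in a
    shuffled order; probe gaps are uniform on {probe_min..probe_max}.  On
    forced trials the single presented option alternates between the
    currently-high and currently-low option with equal frequency, in shuffled
    order.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_trials

    reversals = []
    t = 0
    while True:
        t += int(rng.integers(config.reversal_min, config.reversal_max + 1))
        if t > n:
            break
        reversals.append(t)
    reversal_trials = np.array(reversals, dtype=int)

    high_option = []
    current = "A"
    flips = set(reversals)
    for j in range(1, n + 1):
        if j in flips:
            current = "B" if current == "A" else "A"
        high_option.append(current)

    n_free = round(config.free_choice_fraction * n)
    types = np.array(["free"] * n_free + ["forced"] * (n - n_free))
    rng.shuffle(types)
    choice_types = list(types)

    # forced trials present high/low with equal frequency, pseudo-random order
    n_forced = n - n_free
    forced_levels = np.array(["high"] * (n_forced // 2) + ["low"] * (n_forced - n_forced // 2))
    rng.shuffle(forced_levels)
    forced_options = [""] * n
    fi = 0
    for j in range(n):
        if choice_types[j] == "forced":
            level = forced_levels[fi]
            fi += 1
            if level == "high":
                forced_options[j] = high_option[j]
            else:
                forced_options[j] = "B" if high_option[j] == "A" else "A"

    probes = []
    t = 0
    while True:
        t += int(rng.integers(config.probe_min, config.probe_max + 1))
        if t > n:
            break
        probes.append(t)
    probe_trials = np.array(probes, dtype=int)

    per_block = int(np.ceil(n / config.n_blocks))
    block = np.minimum((np.arange(n) // per_block) + 1, config.n_blocks)
    return Schedule(
        n_trials=n,
        reversal_trials=reversal_trials,
        choice_types=choice_types,
        forced_options=forced_options,
        probe_trials=probe_trials,
        high_option=high_option,
        block=block.astype(int),
    )


def simulate_agent_choices(
    schedule: Schedule,
    agent: AgentSpec,
    config: TaskConfig,
    rng: np.random.Generator,
):
    """Simulate choices and reward points for one agent over a schedule.

    Option values start at the midpoint of the two reward means and are
    updated by a prediction-error delta rule from observed points; free
    choices are sampled from a softmax over values, forced choices take the
    single presented option.  Returns ``(chosen_options, reward_points)``.
    """
    v = {opt: 0.5 * (config.reward_mean_high + config.reward_mean_low) for opt in "AB"}
    chosen: list[str] = []
    points = np.empty(schedule.n_trials, dtype=float)
    beta = agent.inverse_temperature
    for j in range(schedule.n_trials):
        if schedule.choice_types[j] == "forced":
            c = schedule.forced_options[j]
        else:
            p_a = 1.0 / (1.0 + np.exp(-beta * (v["A"] - v["B"])))
            c = "A" if rng.random() < p_a else "B"
        mean = (
            config.reward_mean_high
            if c == schedule.high_option[j]
            else config.reward_mean_low
        )
        r = mean + config.reward_sd * rng.standard_normal()
        v[c] += agent.learning_rate * (r - v[c])
        chosen.append(c)
        points[j] = r
    return chosen, points


def simulate_trial_outcomes(
    schedule: Schedule,
    agent: AgentSpec,
    staircase_state: StaircaseState,
    rng: np.random.Generator,
):
    """Simulate collisions and cursor speeds with the staircase running in-task.

    Per trial: success probability is the agent's logistic psychometric
    function of the current staircased speed; collision = 1 - success; the
    staircase then folds in the outcome.  Returns
    ``(collisions, speeds, final_state)``.
    """
    performer = agent.performer
    n = schedule.n_trials
    collisions = np.empty(n, dtype=int)
    speeds = np.empty(n, dtype=float)
    state = staircase_state
    for j in range(n):
        speeds[j] = state.current_speed
        p = performer.success_probability(state.current_speed)
        success = int(rng.random() < p)
        collisions[j] = 1 - success
        state = pest_update(state, success)
    return collisions, speeds, state


def generate_ratings(
    trials: list[TrialRecord],
    params: HappinessParams,
    model: ModelSpec,
    rng_seed: int | np.random.Generator = 0,
    pre_task: bool = True,
) -> RatingSeries:
    """Generate happiness ratings at probe trials from the affective model.

    At each probe the rating is the model prediction plus N(0, sigma) noise.
    Raw-mode ratings are clipped to the physical rating line (0-100);
    standardized ratings are left unclipped.  A pre-task rating (baseline
    plus noise in raw mode; noise only in standardized mode) is emitted but
    flagged separately.
    """
    params.validate(model)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    regs = build_regressors(trials)
    pred = predict_happiness(model, params, regs)
    ratings = pred + params.sigma * rng.standard_normal(pred.size)
    baseline = params.w0 if model.include_baseline else 0.0
    pre = baseline + params.sigma * rng.standard_normal() if pre_task else None
    if model.rating_mode == "raw":
        ratings = np.clip(ratings, *RATING_SCALE)
        if pre is not None:
            pre = float(np.clip(pre, *RATING_SCALE))
    return RatingSeries(
        trial_index=regs.probe_trials,
        rating=ratings,
        mode=model.rating_mode,
        pre_task_rating=pre,
    )


def simulate_session(
    config: TaskConfig,
    agent: AgentSpec,
    model: ModelSpec | None = None,
    rng_seed: int | None = None,
    calibration_trials: int = 60,
):
    """Simulate one full session: calibration, task trials and ratings.

    A 60-trial PEST calibration (against the agent's own psychometric
    function) precedes the task; the staircase keeps running during the task.
    Returns ``(trials, ratings)``.  All randomness flows from one generator
    seeded by ``rng_seed`` (falling back to ``config.rng_seed``).
    """
    if model is None:
        model = ModelSpec()
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(
        replace(config, rng_seed=int(rng.integers(0, 2**31)))
    )
    chosen, points = simulate_agent_choices(schedule, agent, config, rng)

    state = init_staircase(initial_speed=agent.psychometric_threshold)
    state, _, _ = run_calibration(agent.performer, calibration_trials, state, rng)
    collisions, speeds, _ = simulate_trial_outcomes(schedule, agent, state, rng)

    probe_set = set(schedule.probe_trials.tolist())
    trials = [
        TrialRecord(
            trial_index=j + 1,
            block=int(schedule.block[j]),
            choice_type=schedule.choice_types[j],
            high_option_identity=schedule.high_option[j],
            chosen_option=chosen[j],
            reward_points=float(points[j]),
            collision=int(collisions[j]),
            cursor_speed=float(speeds[j]),
            probe_after=int((j + 1) in probe_set),
        )
        for j in range(schedule.n_trials)
    ]
    ratings = generate_ratings(trials, agent.happiness_params, model, rng)
    return trials, ratings
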