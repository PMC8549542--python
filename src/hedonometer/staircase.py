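"""PEST adaptive staircase for cursor speed.

Parameter Estimation by Sequential Testing (Taylor & Creelman 1967) holds the
probability of a barrier-free run near a target (default 0.70) by adjusting
cursor speed: faster cursors are harder to steer, so an excess of successes
raises the speed and a deficit lowers it.

Decisions follow the Wald sequential rule: trials accumulate in a run until
the deviation |successes - target_p * trials| exceeds the limit ``wald_w``,
at which point the speed steps and the run restarts.  Step sizes follow the
classic PEST heuristics: halve on a direction reversal; a second step in the
same direction keeps the step size; the third and later same-direction steps
double it — except that when the most recent reversal immediately followed a
doubled step, the doubling is postponed by one step (the classic
"no doubling on the step after a reversal-adjacent double" exception).
Step size and speed are clamped to configured bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StaircaseState",
    "LogisticPerformer",
    "init_staircase",
    "pest_update",
    "run_calibration",
]


@dataclass(frozen=True)
class StaircaseState:
    """Immutable staircase state; :func:`pest_update` returns a new state."""

    current_speed: float
    step_size: float
    last_direction: str = "none"  # {"up", "down", "none"}
    doubled_last: bool = False
    #: set when the latest reversal immediately followed a doubled step,
    #: postponing the next doubling by one step
    postpone_double: bool = False
    steps_in_direction: int = 0
    successes_in_run: int = 0
    trials_in_run: int = 0
    target_p: float = 0.70
    wald_w: float = 1.0
    min_step: float = 0.0
    max_step: float = np.inf
    speed_bounds: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        lo, hi = self.speed_bounds
        if not lo < hi:
            raise ValueError("speed_bounds must be ordered (lo < hi)")
        if not 0.0 < self.target_p < 1.0:
            raise ValueError("target_p must lie strictly in (0, 1)")
        if not lo <= self.current_speed <= hi:
            raise ValueError("current_speed outside speed_bounds")
        if not 0 < self.min_step <= self.max_step:
            raise ValueError("require 0 < min_step <= max_step")
        if not self.min_step <= self.step_size <= self.max_step:
            raise ValueError("step_size outside [min_step, max_step]")


def init_staircase(
    target_p: float = 0.70,
    initial_speed: float = 1.0,
    initial_step: float | None = None,
    bounds: tuple[float, float] = (0.05, 5.0),
    wald_w: float = 1.0,
    min_step: float | None = None,
    max_step: float | None = None,
) -> StaircaseState:
    """Construct a staircase state with empty run counters.

    Defaults follow standard PEST practice: the initial step is 10% of the
    initial speed, the maximum step half the initial speed and the minimum
    step 1% of it.
    """
    if initial_step is None:
        initial_step = 0.10 * initial_speed
    if max_step is None:
        max_step = 0.5 * initial_speed
    if min_step is None:
        min_step = 0.01 * initial_speed
    return StaircaseState(
        current_speed=float(initial_speed),
        step_size=float(initial_step),
        target_p=float(target_p),
        wald_w=float(wald_w),
        min_step=float(min_step),
        max_step=float(max_step),
        speed_bounds=(float(bounds[0]), float(bounds[1])),
    )


def pest_update(state: StaircaseState, success: int) -> StaircaseState:
    """Fold one trial outcome into the staircase; pure function of (state, success).

    The run counters accumulate until the Wald deviation limit is crossed;
    only then does the speed step (excess successes => faster/harder, deficit
    => slower/easier) and the step-size heuristics apply.
    """
    successes = state.successes_in_run + int(bool(success))
    trials = state.trials_in_run + 1
    deviation = successes - state.target_p * trials
    if abs(deviation) <= state.wald_w:
        return replace(state, successes_in_run=successes, trials_in_run=trials)

    direction = "up" if deviation > 0 else "down"
    step = state.step_size
    doubled = False
    postpone = state.postpone_double
    if state.last_direction in ("up", "down") and direction != state.last_direction:
        step = step / 2.0
        steps_in_dir = 1
        postpone = state.doubled_last  # reversal right after a double
    else:
        steps_in_dir = state.steps_in_direction + 1 if state.last_direction == direction else 1
        if steps_in_dir >= 3:
            if postpone:
                postpone = False  # take one extra same-size step first
            else:
                step = step * 2.0
                doubled = True
    step = float(np.clip(step, state.min_step, state.max_step))
    delta = step if direction == "up" else -step
    lo, hi = state.speed_bounds
    speed = float(np.clip(state.current_speed + delta, lo, hi))
    return replace(
        state,
        current_speed=speed,
        step_size=step,
        last_direction=direction,
        doubled_last=doubled,
        postpone_double=postpone,
        steps_in_direction=steps_in_dir,
        successes_in_run=0,
        trials_in_run=0,
    )


@dataclass(frozen=True)
class LogisticPerformer:
    """Simulated performer: success probability falls logistically with speed.

    P(success | speed) = 1 / (1 + exp(slope * (speed - threshold))); the
    threshold is the speed at which success probability is 0.5 and the slope
    must be positive so that faster always means harder.
    """

    threshold: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("psychometric slope must be positive (faster = harder)")

    def success_probability(self, speed: float) -> float:
        if not np.isfinite(speed):
            raise ValueError("non-finite cursor speed signals staircase corruption")
        return float(1.0 / (1.0 + np.exp(self.slope * (speed - self.threshold))))

    def speed_at(self, p: float) -> float:
        """Speed at which the success probability equals *p* (inverse logistic)."""
        return self.threshold - np.log(p / (1.0 - p)) / self.slope


def run_calibration(
    performer,
    n_trials: int = 60,
    state: StaircaseState | None = None,
    rng: np.random.Generator | None = None,
):
    """Run *n_trials* staircased trials against a performer.

    The performer maps speed to success probability (monotone decreasing).
    Returns ``(final_state, successes, speeds)`` where the arrays record the
    trajectory.  The pre-task 60-trial calibration and the continued in-task
    adjustment are the same operation on different trial streams.
    """
    if state is None:
        state = init_staircase()
    if rng is None:
        rng = np.random.default_rng()
    successes = np.empty(n_trials, dtype=int)
    speeds = np.empty(n_trials, dtype=float)
    for i in range(n_trials):
        speeds[i] = state.current_speed
        p = performer.success_probability(state.current_speed)
        successes[i] = int(rng.random() < p)
        state = pest_update(state, successes[i])
    return state, successes, speeds
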