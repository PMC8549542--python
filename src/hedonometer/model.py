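"""Momentary-happiness model.

Happiness at a probe after trial ``t`` is modelled as a weighted sum of
exponentially discounted event histories,

    Happiness(t) = [w0] + w_reward * sum_{j<=t} gamma^(t-j) Reward_j
                        + w_performance * sum_{j<=t} gamma^(t-j) Performance_j

where ``Reward_j`` is the z-scored points outcome of the option selected on
trial ``j``, ``Performance_j`` is the z-scored indicator of a barrier-free
(collision-less) run on trial ``j``, and the forgetting factor
``0 <= gamma <= 1`` discounts distal relative to recent events (gamma = 0
means only the most recent trial matters).  Fits to raw ratings include the
baseline-mood intercept ``w0``; fits to within-subject standardized ratings
omit it.  The observation model adds Gaussian noise with SD ``sigma``.

Four canonical model variants are exposed (see :data:`CANONICAL_MODELS`):
reward only, performance only, both terms with a shared gamma, and both
terms with separate gammas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ModelSpec",
    "HappinessParams",
    "RegressorSet",
    "CANONICAL_MODELS",
    "zscore",
    "build_regressors",
    "decayed_sum",
    "decayed_series",
    "predict_happiness",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one happiness-model variant.

    Parameters
    ----------
    terms
        Subset of ``{"reward", "performance"}``; which event histories enter
        the model.
    shared_gamma
        If False, reward and performance histories carry separate forgetting
        factors (only meaningful when both terms are present).
    include_baseline
        Whether the baseline-mood intercept ``w0`` is estimated.  True for
        raw-rating fits, False for standardized-rating fits.
    rating_mode
        ``"raw"`` or ``"zscored"``; the scale the ratings are modelled on.
    """

    terms: tuple[str, ...] = ("reward", "performance")
    shared_gamma: bool = True
    include_baseline: bool = False
    rating_mode: str = "zscored"

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms:
            raise ValueError("ModelSpec.terms must be non-empty")
        unknown = set(terms) - {"reward", "performance"}
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        if not self.shared_gamma and len(terms) < 2:
            raise ValueError("separate gammas require both reward and performance terms")
        if self.rating_mode not in ("raw", "zscored"):
            raise ValueError(f"invalid rating_mode {self.rating_mode!r}")
        if self.include_baseline != (self.rating_mode == "raw"):
            raise ValueError("include_baseline must be True iff rating_mode is 'raw'")

    @property
    def n_structural_params(self) -> int:
        """Count of structural parameters (weights + gamma(s) + w0; sigma excluded)."""
        k = len(self.terms)
        k += 1 if self.shared_gamma else 2
        if self.include_baseline:
            k += 1
        return k

    @property
    def gamma_names(self) -> tuple[str, ...]:
        if self.shared_gamma:
            return ("gamma",)
        return ("gamma_reward", "gamma_performance")


#: Canonical four-model family, on standardized ratings.
CANONICAL_MODELS: dict[str, ModelSpec] = {
    "reward": ModelSpec(terms=("reward",)),
    "performance": ModelSpec(terms=("performance",)),
    "reward_performance": ModelSpec(terms=("reward", "performance")),
    "reward_performance_sepgamma": ModelSpec(
        terms=("reward", "performance"), shared_gamma=False
    ),
}


@dataclass
class HappinessParams:
    """Parameter vector for one :class:`ModelSpec`.

    Weights are in rating units per z-scored regressor unit; ``gamma`` (or the
    ``gamma_reward``/``gamma_performance`` pair) is the dimensionless
    forgetting factor in [0, 1]; ``sigma`` is the Gaussian rating-noise SD in
    rating units.  Fields not demanded by the spec are left as None.
    """

    w0: float | None = None
    w_reward: float | None = None
    w_performance: float | None = None
    gamma: float | None = None
    gamma_reward: float | None = None
    gamma_performance: float | None = None
    sigma: float = 0.0

    def validate(self, spec: ModelSpec) -> None:
        """Raise ValueError unless exactly the fields demanded by *spec* are set."""
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if spec.include_baseline and self.w0 is None:
            raise ValueError("raw-mode model requires w0")
        for term in ("reward", "performance"):
            w = getattr(self, f"w_{term}")
            if term in spec.terms and w is None:
                raise ValueError(f"missing weight w_{term} for active term")
        gammas = [getattr(self, g) for g in spec.gamma_names]
        if any(g is None for g in gammas):
            raise ValueError(f"missing forgetting factor(s) {spec.gamma_names}")
        for g in gammas:
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"forgetting factor {g} outside [0, 1]")

    def gamma_for(self, term: str, spec: ModelSpec) -> float:
        if spec.shared_gamma:
            return float(self.gamma)
        return float(getattr(self, f"gamma_{term}"))

    def weight_for(self, term: str) -> float:
        return float(getattr(self, f"w_{term}"))


@dataclass
class RegressorSet:
    """Per-trial z-scored event regressors plus probe alignment.

    ``reward`` and ``performance`` each hold one entry per trial (1-based
    trial j maps to index j-1).  ``probe_trials`` are the 1-based indices of
    trials followed by a happiness probe.
    """

    reward: np.ndarray
    performance: np.ndarray
    probe_trials: np.ndarray

    def __post_init__(self) -> None:
        self.reward = np.asarray(self.reward, dtype=float)
        self.performance = np.asarray(self.performance, dtype=float)
        self.probe_trials = np.asarray(self.probe_trials, dtype=int)
        if self.reward.shape != self.performance.shape:
            raise ValueError("reward and performance regressors differ in length")
        n = self.reward.size
        if self.probe_trials.size and (
            self.probe_trials.min() < 1 or self.probe_trials.max() > n
        ):
            raise ValueError("probe trial index outside the trial range")

    def column(self, term: str) -> np.ndarray:
        return getattr(self, term)

    @property
    def n_trials(self) -> int:
        return int(self.reward.size)


def zscore(x: np.ndarray, name: str = "vector") -> np.ndarray:
    """Standardize with the population-SD convention (divide by n).

    Raises ValueError naming the degenerate column when the SD is zero.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"cannot z-score degenerate column {name!r} (zero variance)")
    return (x - x.mean()) / sd


def build_regressors(trials, ratings=None) -> RegressorSet:
    """Build the z-scored Reward and Performance regressors for one subject.

    Parameters
    ----------
    trials
        Sequence of trial records with ``trial_index``, ``reward_points``,
        ``collision`` and ``probe_after`` attributes, contiguous from 1.
        Both free and forced trials enter the z-scoring.
    ratings
        Optional rating series; when given, its probe trials are used for
        alignment (they must be a subset of the trial indices), otherwise the
        ``probe_after`` flags are.

    Performance is coded 1 for a collision-free trial and 0 otherwise, then
    z-scored like the reward points.
    """
    idx = np.array([t.trial_index for t in trials], dtype=int)
    if idx.size == 0 or idx[0] != 1 or np.any(np.diff(idx) != 1):
        raise ValueError("trial indices must be contiguous from 1")
    points = np.array([t.reward_points for t in trials], dtype=float)
    success = np.array([1.0 - t.collision for t in trials], dtype=float)
    if ratings is not None:
        probe_trials = np.asarray(ratings.trial_index, dtype=int)
        if not np.isin(probe_trials, idx).all():
            raise ValueError("rating probe trials are not a subset of trial indices")
    else:
        probe_trials = idx[np.array([bool(t.probe_after) for t in trials])]
    return RegressorSet(
        reward=zscore(points, "reward"),
        performance=zscore(success, "performance"),
        probe_trials=probe_trials,
    )


def decayed_sum(x: np.ndarray, gamma: float, t: int) -> float:
    """Exponentially discounted history sum ``sum_{j=1..t} gamma^(t-j) x_j``.

    Evaluated by the recursion ``S_t = gamma * S_{t-1} + x_t`` for numerical
    stability.  ``t`` is 1-based.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if not 1 <= t <= x.size:
        raise ValueError(f"trial index t={t} outside 1..{x.size}")
    s = 0.0
    for j in range(t):
        s = gamma * s + x[j]
    return float(s)


def decayed_series(x: np.ndarray, gamma: float) -> np.ndarray:
    """Vector of discounted sums S_t for every t, via a first-order IIR filter."""
    x = np.asarray(x, dtype=float)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return lfilter([1.0], [1.0, -gamma], x)


def predict_happiness(
    spec: ModelSpec, params: HappinessParams, regressors: RegressorSet
) -> np.ndarray:
    """Noise-free model prediction at each probe trial.

    Returns one predicted rating per entry of ``regressors.probe_trials``;
    Gaussian observation noise is *not* added here.
    """
    params.validate(spec)
    at = regressors.probe_trials - 1
    pred = np.zeros(at.size, dtype=float)
    if spec.include_baseline:
        pred += params.w0
    for term in spec.terms:
        g = params.gamma_for(term, spec)
        pred += params.weight_for(term) * decayed_series(regressors.column(term), g)[at]
    return pred
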