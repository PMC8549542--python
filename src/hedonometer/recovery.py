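"""Parameter-recovery and model-recovery pipelines on synthetic cohorts.

Parameter recovery simulates a cohort of agents with known ("true")
happiness-model parameters, generates noisy ratings, re-estimates the
parameters with the same fitting procedure applied to real data, and reports
Spearman rank correlations between true and estimated values.  Model
recovery simulates cohorts under each candidate generative model, fits all
candidates to each cohort, and tabulates which model wins by BIC.

Because subject-level estimates from the original cohort are not available,
the default cohort samples per-agent parameters from normal distributions
matched to the printed group mean ± SEM (between-agent SD = SEM * sqrt(33)),
with gamma truncated to [0, 1] and sigma truncated positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult, compare_models, fit_model
from .model import CANONICAL_MODELS, HappinessParams, ModelSpec, build_regressors
from .task import AgentSpec, RatingSeries, TaskConfig, TrialRecord, simulate_session

__all__ = [
    "CohortSpec",
    "AgentRecord",
    "RecoveryResult",
    "GROUP_MEAN_PARAMS",
    "DEFAULT_PARAMETER_DISTRIBUTIONS",
    "sample_agent_params",
    "simulate_cohort",
    "fit_cohort",
    "parameter_recovery",
    "model_recovery",
]

#: Group-mean parameters of the standardized reward+performance model
#: (weights in z-scored rating units, gamma dimensionless, sigma in z-scored
#: rating units).
GROUP_MEAN_PARAMS = {"w_reward": 0.39, "w_performance": 0.18, "gamma": 0.48, "sigma": 0.85}

#: Between-agent spreads: SD = SEM * sqrt(33) from the printed group mean ± SEM
#: (SEMs 0.04, 0.03, 0.05, 0.02 for w_reward, w_performance, gamma, sigma).
DEFAULT_PARAMETER_DISTRIBUTIONS = {
    "w_reward": (0.39, 0.04 * np.sqrt(33)),
    "w_performance": (0.18, 0.03 * np.sqrt(33)),
    "gamma": (0.48, 0.05 * np.sqrt(33)),
    "sigma": (0.85, 0.02 * np.sqrt(33)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Simulated-cohort description for recovery pipelines.

    ``parameter_distributions`` maps parameter name to (mean, SD); a zero SD
    gives a point-mass cohort (flagged: rank-recovery correlations are then
    undefined).  gamma draws are truncated to [0, 1], sigma draws to (0, inf).
    """

    n_agents: int = 33
    parameter_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_PARAMETER_DISTRIBUTIONS)
    )
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("a cohort needs at least 2 agents")
        for name, (_, sd) in self.parameter_distributions.items():
            if sd < 0:
                raise ValueError(f"negative SD for parameter {name!r}")


@dataclass
class AgentRecord:
    """One simulated agent: ground truth, seed and session data."""

    agent_index: int
    seed: int
    true_params: HappinessParams
    trials: list[TrialRecord]
    ratings: RatingSeries


@dataclass
class RecoveryResult:
    """True-vs-estimated parameter vectors and their rank correlations."""

    model: ModelSpec
    true: pd.DataFrame  # one row per recovered agent, one column per parameter
    estimated: pd.DataFrame
    spearman: dict  # parameter -> Spearman rho (NaN when truth is degenerate)
    n_failed: int = 0


def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf):
    """Draw from N(mean, sd) truncated to [lo, hi] by resampling."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = mean + sd * rng.standard_normal()
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal resampling failed to land inside bounds")


def _param_names(model: ModelSpec) -> list[str]:
    names = [f"w_{t}" for t in model.terms]
    names += list(model.gamma_names)
    names.append("sigma")
    if model.include_baseline:
        names.insert(0, "w0")
    return names


def sample_agent_params(
    spec: CohortSpec, model: ModelSpec, rng: np.random.Generator
) -> HappinessParams:
    """Sample one agent's true parameters from the cohort distributions."""
    dists = spec.parameter_distributions
    p = HappinessParams()
    for name in _param_names(model):
        if name in dists:
            mean, sd = dists[name]
        elif name.startswith("gamma") and "gamma" in dists:
            mean, sd = dists["gamma"]  # separate gammas share the gamma distribution
        else:
            raise KeyError(f"no distribution for parameter {name!r}")
        lo, hi = -np.inf, np.inf
        if name.startswith("gamma"):
            lo, hi = 0.0, 1.0
        elif name == "sigma":
            lo = 1e-12
        elif name == "w0":
            lo, hi = 0.0, 100.0
        setattr(p, name, _truncated_normal(rng, mean, sd, lo, hi))
    return p


def simulate_cohort(spec: CohortSpec, model: ModelSpec | None = None) -> list[AgentRecord]:
    """Simulate a cohort of independent agents under one generative model.

    Each agent gets its own task realization (schedule, choices, staircased
    performance) and ratings generated with that agent's own noise SD.  Agent
    seeds are spawned from the cohort seed so agents are independent and the
    cohort is reproducible.
    """
    if model is None:
        model = CANONICAL_MODELS["reward_performance"]
    rng = np.random.default_rng(spec.seed)
    agent_seeds = rng.integers(0, 2**31, size=spec.n_agents)
    records = []
    for i in range(spec.n_agents):
        true = sample_agent_params(spec, model, rng)
        agent = AgentSpec(happiness_params=true)
        trials, ratings = simulate_session(
            spec.task, agent, model, rng_seed=int(agent_seeds[i])
        )
        records.append(
            AgentRecord(
                agent_index=i,
                seed=int(agent_seeds[i]),
                true_params=true,
                trials=trials,
                ratings=ratings,
            )
        )
    return records


def fit_cohort(
    cohort: list[AgentRecord], model: ModelSpec, restarts: int = 10
) -> list[FitResult | None]:
    """Fit one model to every agent; a failed fit yields None in its slot."""
    fits: list[FitResult | None] = []
    for rec in cohort:
        try:
            regs = build_regressors(rec.trials, rec.ratings)
            fits.append(fit_model(rec.ratings, regs, model, restarts=restarts))
        except ValueError:
            fits.append(None)
    return fits


def parameter_recovery(
    cohort: list[AgentRecord], model: ModelSpec, restarts: int = 10
) -> RecoveryResult:
    """Re-estimate every agent and correlate true vs estimated parameters.

    The estimated sigma is the residual SD sqrt(RSS/n), so the sigma row of
    the result doubles as the residual-SD-vs-noise check.  Agents whose fit
    fails are excluded and counted.
    """
    fits = fit_cohort(cohort, model, restarts=restarts)
    names = _param_names(model)
    rows_t, rows_e = [], []
    n_failed = 0
    for rec, fit in zip(cohort, fits):
        if fit is None:
            n_failed += 1
            continue
        rows_t.append({k: getattr(rec.true_params, k) for k in names})
        rows_e.append({k: getattr(fit.params, k) for k in names})
    true = pd.DataFrame(rows_t, columns=names)
    est = pd.DataFrame(rows_e, columns=names)
    rho = {}
    for k in names:
        if true[k].nunique() < 2 or est[k].nunique() < 2:
            rho[k] = float("nan")  # degenerate: no rank signal
        else:
            rho[k] = float(stats.spearmanr(true[k], est[k]).statistic)
    return RecoveryResult(model=model, true=true, estimated=est, spearman=rho, n_failed=n_failed)


def model_recovery(
    specs: dict[str, ModelSpec] | None = None,
    cohort_template: CohortSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-recovery confusion matrix (generative model x best-BIC model).

    For each generative model a cohort is simulated, all candidate models are
    fit to every agent, and each agent is assigned to its lowest-BIC model;
    an extra ``cohort_winner`` column records the summed-BIC winner.
    Rows (generative models) sum to n_agents over the candidate columns.
    """
    if specs is None:
        specs = CANONICAL_MODELS
    if cohort_template is None:
        cohort_template = CohortSpec()
    names = list(specs)
    counts = pd.DataFrame(0, index=names, columns=names)
    cohort_winner = {}
    rng = np.random.default_rng(seed)
    for gen_name in names:
        cohort = simulate_cohort(
            replace(cohort_template, seed=int(rng.integers(0, 2**31))),
            specs[gen_name],
        )
        fits_by_model = {m: fit_cohort(cohort, specs[m]) for m in names}
        for i in range(len(cohort)):
            bics = {m: fits_by_model[m][i].bic for m in names if fits_by_model[m][i]}
            counts.loc[gen_name, min(bics, key=bics.get)] += 1
        complete = {m: f for m, f in fits_by_model.items() if all(x is not None for x in f)}
        cohort_winner[gen_name] = compare_models(complete).winner
    counts["cohort_winner"] = pd.Series(cohort_winner)
    return counts
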