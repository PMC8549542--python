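"""Per-subject least-squares estimation and BIC model comparison.

Parameters are estimated by minimizing the residual sum of squares (RSS)
between observed and predicted happiness ratings.  The objective is profiled:
at any fixed forgetting factor(s) the weights (and baseline) enter linearly,
so the inner subproblem is ordinary least squares and only the gamma(s) need
a bounded nonlinear search, run from multiple starts with a deterministic
tie-break.

Model comparison uses the Gaussian profile-likelihood BIC,

    BIC = n * ln(RSS / n) + k * ln(n),

with ``k`` the count of structural parameters (weights + gamma(s) + w0 when
present; the noise SD is excluded from ``k``), summed across subjects.
Ratings are standardized within subject before comparison so that subjects
with greater rating variance do not dominate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import HappinessParams, ModelSpec, RegressorSet, decayed_series, zscore
from .task import RatingSeries

__all__ = [
    "FitResult",
    "ComparisonTable",
    "WEIGHT_BOUNDS",
    "BASELINE_BOUNDS",
    "profile_rss",
    "fit_model",
    "compute_bic",
    "compare_models",
    "trim_and_detrend",
    "standardize_ratings",
    "likelihood_ratio_test",
]

#: Weight bounds for standardized-rating fits; baseline bounds for raw fits.
WEIGHT_BOUNDS = (-10.0, 10.0)
BASELINE_BOUNDS = (0.0, 100.0)

#: Convergence tolerance on the profiled RSS.
RSS_TOL = 1e-8

#: Default multi-start gamma initializations.
GAMMA_STARTS = np.arange(0.05, 1.0, 0.10)


@dataclass
class FitResult:
    """One subject x model fit: parameters plus goodness-of-fit summaries."""

    spec: ModelSpec
    params: HappinessParams
    rss: float
    r_squared: float
    n_ratings: int
    bic: float
    n_restarts_used: int
    converged: bool


@dataclass
class ComparisonTable:
    """Cohort-level model comparison: per-model k, mean r², summed BIC, ΔBIC."""

    table: pd.DataFrame  # index: model name; columns: n_params, mean_r2, bic, delta_bic

    @property
    def winner(self) -> str:
        return str(self.table["bic"].idxmin())


def _design_matrix(
    spec: ModelSpec, regressors: RegressorSet, gammas: np.ndarray
) -> np.ndarray:
    at = regressors.probe_trials - 1
    cols = []
    if spec.include_baseline:
        cols.append(np.ones(at.size))
    for term, g in zip(spec.terms, _expand_gammas(spec, gammas)):
        cols.append(decayed_series(regressors.column(term), g)[at])
    return np.column_stack(cols)


def _expand_gammas(spec: ModelSpec, gammas: np.ndarray) -> np.ndarray:
    """Map the free gamma vector to one gamma per term."""
    if spec.shared_gamma:
        return np.repeat(gammas[0], len(spec.terms))
    return np.asarray(gammas, dtype=float)


def profile_rss(
    spec: ModelSpec,
    regressors: RegressorSet,
    y: np.ndarray,
    gammas: np.ndarray,
):
    """Inner least-squares solution at fixed gamma(s).

    Returns ``(rss, coefficients)`` where the coefficient vector is ordered
    as [w0 if present, weights in term order].  Falls back to a bounded
    linear solve only if the unconstrained optimum escapes the weight bounds
    (which does not happen on sane data).
    """
    x = _design_matrix(spec, regressors, np.atleast_1d(np.asarray(gammas, dtype=float)))
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    lo, hi = [], []
    if spec.include_baseline:
        lo.append(BASELINE_BOUNDS[0])
        hi.append(BASELINE_BOUNDS[1])
    lo += [WEIGHT_BOUNDS[0]] * len(spec.terms)
    hi += [WEIGHT_BOUNDS[1]] * len(spec.terms)
    lo, hi = np.array(lo), np.array(hi)
    if np.any(coef < lo) or np.any(coef > hi):
        res = optimize.lsq_linear(x, y, bounds=(lo, hi))
        coef = res.x
    resid = y - x @ coef
    return float(resid @ resid), coef


def fit_model(
    ratings: RatingSeries,
    regressors: RegressorSet,
    spec: ModelSpec,
    restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Estimate happiness-model parameters for one subject by bounded RSS minimization.

    Multi-start over gamma (``restarts`` starts spread over (0, 1); weights
    from the closed-form inner solution at each gamma); best-of-restarts with
    a deterministic tie-break (lowest RSS, then lowest gamma).  ``sigma`` is
    the maximum-likelihood residual SD ``sqrt(RSS / n)``; ``r_squared`` is
    ``1 - RSS / TSS`` with TSS about the rating mean.
    """
    y = np.asarray(ratings.rating, dtype=float)
    n = y.size
    k = spec.n_structural_params
    if n < k + 5:
        raise ValueError(f"need at least {k + 5} ratings to fit {k} parameters, got {n}")
    if not np.array_equal(np.asarray(ratings.trial_index), regressors.probe_trials):
        raise ValueError("ratings and regressors disagree on probe trials")

    n_gammas = 1 if spec.shared_gamma else 2
    if n_gammas == 1:
        starts = [np.array([g]) for g in np.linspace(0.05, 0.95, restarts)]
    else:
        side = [0.15, 0.50, 0.85]
        starts = [np.array([a, b]) for a in side for b in side]
        starts.append(np.array([0.48, 0.48]))
        starts = starts[:max(restarts, 1)] if restarts < len(starts) else starts

    def objective(g: np.ndarray) -> float:
        return profile_rss(spec, regressors, y, g)[0]

    best = None
    any_converged = False
    for g0 in starts:
        res = optimize.minimize(
            objective,
            g0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * n_gammas,
            options={"ftol": RSS_TOL, "gtol": 1e-10},
        )
        any_converged = any_converged or bool(res.success)
        cand = (float(res.fun), tuple(np.round(res.x, 12)))
        if best is None or cand < best:
            best = cand
    rss, gammas = best[0], np.array(best[1])
    rss, coef = profile_rss(spec, regressors, y, gammas)

    i = 0
    params = HappinessParams(sigma=math.sqrt(rss / n))
    if spec.include_baseline:
        params.w0 = float(coef[i])
        i += 1
    for term in spec.terms:
        setattr(params, f"w_{term}", float(coef[i]))
        i += 1
    for name, g in zip(spec.gamma_names, gammas):
        setattr(params, name, float(g))

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    fit = FitResult(
        spec=spec,
        params=params,
        rss=rss,
        r_squared=r2,
        n_ratings=n,
        bic=float("nan"),
        n_restarts_used=len(starts),
        converged=any_converged,
    )
    fit.bic = compute_bic(fit)
    return fit


def compute_bic(fit: FitResult) -> float:
    """Gaussian profile-likelihood BIC: ``n ln(RSS/n) + k ln(n)``, sigma excluded from k."""
    if fit.n_ratings <= 0:
        raise ValueError("n_ratings must be positive")
    if fit.rss <= 0:
        raise ValueError("RSS must be strictly positive for a finite BIC")
    n, k = fit.n_ratings, fit.spec.n_structural_params
    return float(n * math.log(fit.rss / n) + k * math.log(n))


def compare_models(cohort_fits: dict[str, list[FitResult]]) -> ComparisonTable:
    """Summed-BIC model comparison across subjects.

    ``cohort_fits`` maps model name to the per-subject fit list; every model
    must cover the same subjects.  Reports per model the structural parameter
    count, the across-subject arithmetic mean r², the summed BIC, and ΔBIC
    from the winner.
    """
    sizes = {name: len(fits) for name, fits in cohort_fits.items()}
    if len(set(sizes.values())) != 1 or 0 in sizes.values():
        raise ValueError(f"unbalanced subject x model fits: {sizes}")
    rows = {}
    for name, fits in cohort_fits.items():
        rows[name] = {
            "n_params": fits[0].spec.n_structural_params,
            "mean_r2": float(np.mean([f.r_squared for f in fits])),
            "bic": float(np.sum([f.bic for f in fits])),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["delta_bic"] = table["bic"] - table["bic"].min()
    return ComparisonTable(table=table)


def trim_and_detrend(
    ratings: RatingSeries,
    trim_fraction: float = 0.10,
    detrend: bool = False,
    min_remaining: int = 8,
) -> RatingSeries:
    """Robustness preprocessing: drop the earliest ratings and optionally detrend.

    Drops the first ``ceil(trim_fraction * n)`` ratings; with ``detrend``,
    removes the least-squares linear trend in probe order from the remainder.
    """
    n = ratings.n
    n_drop = math.ceil(trim_fraction * n)
    if n - n_drop < min_remaining:
        raise ValueError(
            f"trimming {n_drop} of {n} ratings leaves fewer than {min_remaining}"
        )
    idx = ratings.trial_index[n_drop:]
    y = ratings.rating[n_drop:].copy()
    if detrend:
        order = np.arange(y.size, dtype=float)
        slope, intercept = np.polyfit(order, y, 1)
        y = y - (intercept + slope * order)
    return RatingSeries(
        trial_index=idx,
        rating=y,
        mode=ratings.mode,
        pre_task_rating=ratings.pre_task_rating,
    )


def standardize_ratings(ratings: RatingSeries) -> RatingSeries:
    """Within-subject z-scoring of ratings (population-SD convention)."""
    return RatingSeries(
        trial_index=ratings.trial_index.copy(),
        rating=zscore(ratings.rating, "ratings"),
        mode="zscored",
        pre_task_rating=ratings.pre_task_rating,
    )


def likelihood_ratio_test(full: FitResult, reduced: FitResult):
    """Nested-model likelihood-ratio test from Gaussian profile likelihoods.

    Statistic ``n ln(RSS_reduced / RSS_full)`` ~ chi² with df = parameter
    difference; used for per-subject significance of individual weights.
    Returns ``(statistic, df, p_value)``.
    """
    if full.n_ratings != reduced.n_ratings:
        raise ValueError("nested fits must share the same ratings")
    df = full.spec.n_structural_params - reduced.spec.n_structural_params
    if df <= 0:
        raise ValueError("'full' must have more parameters than 'reduced'")
    stat = full.n_ratings * math.log(reduced.rss / full.rss)
    return stat, df, float(stats.chi2.sf(stat, df))
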