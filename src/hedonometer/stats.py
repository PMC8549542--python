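"""Descriptive and inferential behavioral statistics.

Condition splits (happiness after high- vs low-reward outcomes, after clean
vs collision runs) with across-subject Wilcoxon signed-rank tests, Spearman
correlations between per-subject quantities (e.g. baseline mood vs a
questionnaire covariate), and split-half (cross-block) reliability of fitted
model parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitResult
from .task import RatingSeries, TrialRecord

__all__ = [
    "ConditionSplit",
    "condition_split_test",
    "correlate_covariate",
    "split_half_reliability",
    "split_blocks",
]


@dataclass
class ConditionSplit:
    """Across-subject paired comparison of mean happiness by trial condition."""

    condition: str
    labels: tuple[str, str]
    per_subject: pd.DataFrame  # one row per retained subject, one column per label
    group_mean: dict
    group_sem: dict
    statistic: float  # Wilcoxon signed-rank W
    z: float  # normal-approximation z of the signed-rank test
    p_value: float
    n_subjects: int
    n_excluded: int


def _condition_labels(condition: str) -> tuple[str, str]:
    if condition == "reward_level":
        return ("high_reward", "low_reward")
    if condition == "collision":
        return ("no_collision", "collision")
    raise ValueError(f"unknown condition {condition!r}")


def _trial_condition(trial: TrialRecord, condition: str) -> str:
    if condition == "reward_level":
        high = trial.chosen_option == trial.high_option_identity
        return "high_reward" if high else "low_reward"
    return "no_collision" if trial.collision == 0 else "collision"


def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Wilcoxon signed-rank test with a z statistic.

    Uses the normal approximation for the z value (the scale on which the
    group results are reported) while taking the p-value from scipy's default
    mode (exact for small samples without ties).
    """
    d = x - y
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return 0.0, 0.0, 1.0  # all pairs tied: null center
    res = sps.wilcoxon(x, y)
    ranks = sps.rankdata(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_plus - mean) / sd if sd > 0 else 0.0
    return float(res.statistic), float(z), float(res.pvalue)


def condition_split_test(
    subjects: list[tuple[list[TrialRecord], RatingSeries]],
    condition: str = "reward_level",
    window: str = "last_trial",
) -> ConditionSplit:
    """Compare mean happiness after trials of one condition vs the other.

    Each rating is assigned to the condition of the single immediately
    preceding trial (``window="last_trial"``); ``window="since_last_probe"``
    instead averages each rating into every condition present since the
    previous probe, as a sensitivity analysis.  Reward level is defined by
    whether the *chosen* option was the currently high-mean one.  Subjects
    missing a condition are excluded with a warning; the across-subject test
    is a two-sided Wilcoxon signed-rank test on per-subject condition means.
    """
    labels = _condition_labels(condition)
    if window not in ("last_trial", "since_last_probe"):
        raise ValueError(f"unknown window {window!r}")
    rows = []
    n_excluded = 0
    for trials, ratings in subjects:
        by_index = {t.trial_index: t for t in trials}
        sums = {lab: [] for lab in labels}
        prev_probe = 0
        for t_idx, rating in zip(ratings.trial_index, ratings.rating):
            if window == "last_trial":
                conds = [_trial_condition(by_index[int(t_idx)], condition)]
            else:
                conds = {
                    _trial_condition(by_index[j], condition)
                    for j in range(prev_probe + 1, int(t_idx) + 1)
                }
            for c in conds:
                sums[c].append(rating)
            prev_probe = int(t_idx)
        if any(len(v) == 0 for v in sums.values()):
            n_excluded += 1
            warnings.warn("subject lacks one condition; excluded from the paired test")
            continue
        rows.append({lab: float(np.mean(v)) for lab, v in sums.items()})
    per_subject = pd.DataFrame(rows, columns=labels)
    if len(per_subject) < 2:
        raise ValueError("fewer than 2 subjects with both conditions present")
    a = per_subject[labels[0]].to_numpy()
    b = per_subject[labels[1]].to_numpy()
    w, z, p = _wilcoxon_z(a, b)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(v.size))
    return ConditionSplit(
        condition=condition,
        labels=labels,
        per_subject=per_subject,
        group_mean={labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        group_sem={labels[0]: sem(a), labels[1]: sem(b)},
        statistic=w,
        z=z,
        p_value=p,
        n_subjects=len(per_subject),
        n_excluded=n_excluded,
    )


def correlate_covariate(values, covariate, method: str = "spearman"):
    """Rank correlation between a per-subject quantity and a covariate.

    Returns ``(rho, p_value)``; pairs with missing values are dropped first.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size != y.size:
        raise ValueError("values and covariate lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        res = sps.spearmanr(x, y)
    elif method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def split_half_reliability(
    fits_block1: list[FitResult], fits_block2: list[FitResult]
) -> dict:
    """Cross-block Spearman correlation of each fitted parameter.

    Both blocks must be fit with the same model spec; returns a mapping
    parameter name -> (rho, p_value).
    """
    if len(fits_block1) != len(fits_block2) or not fits_block1:
        raise ValueError("blocks must cover the same non-empty subject list")
    spec = fits_block1[0].spec
    if any(f.spec != spec for f in fits_block1 + fits_block2):
        raise ValueError("all fits must share one model spec")
    names = [f"w_{t}" for t in spec.terms] + list(spec.gamma_names) + ["sigma"]
    if spec.include_baseline:
        names.insert(0, "w0")
    out = {}
    for k in names:
        a = [getattr(f.params, k) for f in fits_block1]
        b = [getattr(f.params, k) for f in fits_block2]
        out[k] = correlate_covariate(a, b)
    return out


def split_blocks(trials: list[TrialRecord], ratings: RatingSeries):
    """Split one session into per-block (trials, ratings) halves.

    Trial indices are renumbered from 1 within each block so block-wise
    regressor building and fitting work unchanged; ratings keep only probes
    whose preceding trial falls in the block.
    """
    blocks = sorted({t.block for t in trials})
    out = []
    for b in blocks:
        sub = [t for t in trials if t.block == b]
        offset = sub[0].trial_index - 1
        renumbered = []
        for t in sub:
            t2 = TrialRecord(**{**t.__dict__})
            t2.trial_index = t.trial_index - offset
            renumbered.append(t2)
        keep = [
            i
            for i, idx in enumerate(ratings.trial_index)
            if sub[0].trial_index <= idx <= sub[-1].trial_index
        ]
        rs = RatingSeries(
            trial_index=ratings.trial_index[keep] - offset,
            rating=ratings.rating[keep],
            mode=ratings.mode,
        )
        out.append((renumbered, rs))
    return out
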