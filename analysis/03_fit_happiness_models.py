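"""Fit the four happiness-model variants to every simulated agent.

Per agent and model: bounded least squares on standardized ratings (profile
search over the forgetting factor, closed-form weights), reporting weights,
gamma, residual SD, r^2 and BIC.

Reads results/cohort; writes results/fits.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from hedonometer import CANONICAL_MODELS, build_regressors, fit_model, read_trial_log

COHORT = Path("results/cohort")


def main() -> None:
    subjects = [read_trial_log(p) for p in sorted(COHORT.glob("agent_*"))]
    rows = []
    for i, (trials, ratings) in enumerate(subjects):
        regs = build_regressors(trials, ratings)
        for name, spec in CANONICAL_MODELS.items():
            f = fit_model(ratings, regs, spec)
            rows.append(
                {"agent": i, "model": name, "r_squared": f.r_squared, "rss": f.rss,
                 "bic": f.bic, "n_ratings": f.n_ratings,
                 **{k: v for k, v in dataclasses.asdict(f.params).items() if v is not None}}
            )
    df = pd.DataFrame(rows)
    df.to_csv("results/fits.csv", index=False)
    for name, grp in df.groupby("model"):
        print(f"{name:32s} mean r^2 = {grp.r_squared.mean():.2f}")
    rp = df[df.model == "reward_performance"]
    print(
        "reward+performance group means: "
        f"w_reward {rp.w_reward.mean():.2f}, w_performance {rp.w_performance.mean():.2f}, "
        f"gamma {rp.gamma.mean():.2f}, sigma {rp.sigma.mean():.2f}"
    )
    print("wrote results/fits.csv")


if __name__ == "__main__":
    main()
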