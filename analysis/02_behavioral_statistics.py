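"""Behavioral statistics on the simulated cohort.

Condition splits of happiness by the immediately preceding trial (high- vs
low-reward outcome; collision-free vs collision run) with across-subject
Wilcoxon signed-rank tests, and split-half (block 1 vs block 2) reliability
of the fitted model parameters.

Reads results/cohort (run 01 first); writes results/behavioral_stats.csv.
"""

from pathlib import Path

import pandas as pd

from hedonometer import (
    CANONICAL_MODELS,
    build_regressors,
    condition_split_test,
    fit_model,
    read_trial_log,
    split_blocks,
    split_half_reliability,
)

COHORT = Path("results/cohort")


def main() -> None:
    subjects = [read_trial_log(p) for p in sorted(COHORT.glob("agent_*"))]
    rows = []
    for cond in ("reward_level", "collision"):
        s = condition_split_test(subjects, cond)
        hi, lo = s.labels
        print(
            f"{cond}: {hi} {s.group_mean[hi]:+.3f} ± {s.group_sem[hi]:.3f}, "
            f"{lo} {s.group_mean[lo]:+.3f} ± {s.group_sem[lo]:.3f}, "
            f"z = {s.z:.1f}, p = {s.p_value:.2g} (n = {s.n_subjects})"
        )
        rows.append(
            {"analysis": cond, **{f"mean_{k}": v for k, v in s.group_mean.items()},
             "z": s.z, "p": s.p_value}
        )

    model = CANONICAL_MODELS["reward_performance"]
    fits1, fits2 = [], []
    for trials, ratings in subjects:
        (b1t, b1r), (b2t, b2r) = split_blocks(trials, ratings)[:2]
        fits1.append(fit_model(b1r, build_regressors(b1t, b1r), model))
        fits2.append(fit_model(b2r, build_regressors(b2t, b2r), model))
    rel = split_half_reliability(fits1, fits2)
    for param, (rho, p) in rel.items():
        print(f"split-half reliability {param}: rho = {rho:.2f}, p = {p:.2g}")
        rows.append({"analysis": f"split_half_{param}", "rho": rho, "p": p})

    pd.DataFrame(rows).to_csv("results/behavioral_stats.csv", index=False)
    print("wrote results/behavioral_stats.csv")


if __name__ == "__main__":
    main()
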