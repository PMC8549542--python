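"""Summed-BIC comparison of the four happiness-model variants.

Fits all models to every agent on standardized ratings, sums BIC across the
cohort and reports Delta-BIC from the winner; with data generated from the
shared-gamma reward+performance process, that model should win and the
separate-gamma variant should be penalized for its extra parameter.

Reads results/cohort; writes results/model_comparison.csv.
"""

from pathlib import Path

from hedonometer import (
    CANONICAL_MODELS,
    build_regressors,
    compare_models,
    fit_model,
    read_trial_log,
)

COHORT = Path("results/cohort")


def main() -> None:
    subjects = [read_trial_log(p) for p in sorted(COHORT.glob("agent_*"))]
    fits = {
        name: [
            fit_model(r, build_regressors(t, r), spec) for t, r in subjects
        ]
        for name, spec in CANONICAL_MODELS.items()
    }
    comparison = compare_models(fits)
    table = comparison.table.round({"mean_r2": 2, "bic": 0, "delta_bic": 0})
    print(table.to_string())
    print(f"winner (lowest summed BIC): {comparison.winner}")
    comparison.table.to_csv("results/model_comparison.csv")
    print("wrote results/model_comparison.csv")


if __name__ == "__main__":
    main()
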