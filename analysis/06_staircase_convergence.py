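"""PEST staircase convergence check.

Runs the 60-trial calibration followed by 2,000 staircased trials against
100 simulated performers with heterogeneous logistic psychometric functions
and summarizes the long-run barrier-free success rate (target 70%).

Writes results/staircase.csv.
"""

import numpy as np
import pandas as pd

from hedonometer import LogisticPerformer, init_staircase, run_calibration

SEED = 271828


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(100):
        performer = LogisticPerformer(
            threshold=1.0 + 0.2 * rng.standard_normal(), slope=float(np.exp(rng.normal(1.6, 0.2)))
        )
        state = init_staircase(initial_speed=1.0)
        state, calib_succ, _ = run_calibration(performer, 60, state, rng)
        final, successes, speeds = run_calibration(performer, 2000, state, rng)
        rows.append(
            {
                "performer": i,
                "threshold": performer.threshold,
                "slope": performer.slope,
                "calibration_success": calib_succ.mean(),
                "task_success": successes.mean(),
                "final_speed": final.current_speed,
                "target_speed": performer.speed_at(0.7),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv("results/staircase.csv", index=False)
    print(f"mean post-calibration success: {df.task_success.mean():.1%} (target 70%)")
    print(f"runs inside [65%, 75%]: {((df.task_success >= 0.65) & (df.task_success <= 0.75)).mean():.0%}")
    print(f"mean |final speed - 70% speed|: {np.abs(df.final_speed - df.target_speed).mean():.3f}")
    print("wrote results/staircase.csv")


if __name__ == "__main__":
    main()
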