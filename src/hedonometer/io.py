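"""Tabular I/O, run configuration and end-to-end orchestration.

Trial logs and rating series are plain comma-separated text with a header
row (UTF-8, '.' decimal); floats are written in full-precision repr form so
a write/read round trip reproduces the records exactly.  The run
configuration is YAML, schema-validated with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import compare_models, fit_model, standardize_ratings
from .model import CANONICAL_MODELS, build_regressors
from .recovery import CohortSpec, parameter_recovery, simulate_cohort
from .stats import condition_split_test
from .task import RatingSeries, TaskConfig, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "RATING_COLUMNS",
    "RunConfig",
    "read_trial_log",
    "write_trial_log",
    "load_run_config",
    "run_experiment",
]

TRIAL_COLUMNS = [
    "trial_index",
    "block",
    "choice_type",
    "high_option_identity",
    "chosen_option",
    "reward_points",
    "collision",
    "cursor_speed",
    "probe_after",
]
RATING_COLUMNS = ["trial_index", "rating", "mode"]

SCHEMA_VERSION = "1"


def write_trial_log(trials: list[TrialRecord], ratings: RatingSeries | None, path) -> None:
    """Write one subject's trials (and optionally ratings) under *path*.

    *path* is a directory receiving ``trials.csv`` and ``ratings.csv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [[getattr(t, c) for c in TRIAL_COLUMNS] for t in trials]
    _write_csv(path / "trials.csv", TRIAL_COLUMNS, rows)
    if ratings is not None:
        rows = [
            [int(i), r, ratings.mode]
            for i, r in zip(ratings.trial_index, ratings.rating)
        ]
        if ratings.pre_task_rating is not None:
            # pre-task rating carries trial_index 0 and is excluded from fits
            rows.insert(0, [0, ratings.pre_task_rating, ratings.mode])
        _write_csv(path / "ratings.csv", RATING_COLUMNS, rows)


def _format_cell(v) -> str:
    # full-precision repr for floats so the round trip is exact
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def _write_csv(path: Path, columns, rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(_format_cell(v) for v in row) + "\n")


def read_trial_log(path):
    """Read ``trials.csv`` (and ``ratings.csv`` if present) from a directory.

    Validates the column schema and 1-based contiguous trial indices, and
    that every probe-flagged trial has a rating when ratings exist.  Returns
    ``(trials, ratings)`` with ``ratings`` None for a trials-only log.
    """
    path = Path(path)
    tdf = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(tdf.columns)
    if missing:
        raise ValueError(f"trials.csv missing columns: {sorted(missing)}")
    idx = tdf["trial_index"].to_numpy()
    if idx.size == 0 or idx[0] != 1:
        raise ValueError("trial_index must start at 1")
    jumps = np.nonzero(np.diff(idx) != 1)[0]
    if jumps.size:
        raise ValueError(
            # file line of the offending entry, counting the header line
            f"trial_index not contiguous at row {int(jumps[0]) + 3} "
            f"({int(idx[jumps[0]])} -> {int(idx[jumps[0] + 1])})"
        )
    trials = [
        TrialRecord(
            trial_index=int(r.trial_index),
            block=int(r.block),
            choice_type=str(r.choice_type),
            high_option_identity=str(r.high_option_identity),
            chosen_option=str(r.chosen_option),
            reward_points=float(r.reward_points),
            collision=int(r.collision),
            cursor_speed=float(r.cursor_speed),
            probe_after=int(r.probe_after),
        )
        for r in tdf.itertuples()
    ]
    ratings = None
    rpath = path / "ratings.csv"
    if rpath.exists():
        rdf = pd.read_csv(rpath, float_precision="round_trip")
        missing = set(RATING_COLUMNS) - set(rdf.columns)
        if missing:
            raise ValueError(f"ratings.csv missing columns: {sorted(missing)}")
        pre = None
        pre_rows = rdf["trial_index"] == 0
        if pre_rows.any():
            pre = float(rdf.loc[pre_rows, "rating"].iloc[0])
            rdf = rdf[~pre_rows]
        probe_idx = set(int(t.trial_index) for t in trials if t.probe_after)
        rated_idx = set(int(i) for i in rdf["trial_index"])
        orphans = sorted(probe_idx - rated_idx)
        if orphans:
            raise ValueError(f"probe trial(s) {orphans} have no rating row")
        modes = rdf["mode"].unique()
        if len(modes) != 1:
            raise ValueError("ratings.csv mixes rating modes")
        ratings = RatingSeries(
            trial_index=rdf["trial_index"].to_numpy(dtype=int),
            rating=rdf["rating"].to_numpy(dtype=float),
            mode=str(modes[0]),
            pre_task_rating=pre,
        )
    return trials, ratings


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    task: TaskConfig = field(default_factory=TaskConfig)
    models: list[str] = field(default_factory=lambda: list(CANONICAL_MODELS))
    restarts: int = 10
    n_agents: int = 33
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "stats", "fit", "compare", "recover"]
    )
    output_dir: str = "results/run"
    verbosity: int = 1

    _KNOWN_STAGES = ("simulate", "stats", "fit", "compare", "recover")

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(CANONICAL_MODELS)
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")
        unknown = set(self.stages) - set(self._KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.restarts < 1 or self.n_agents < 2:
            raise ValueError("restarts must be >= 1 and n_agents >= 2")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "task" in raw:
        task_raw = raw["task"]
        task_known = {f.name for f in dataclasses.fields(TaskConfig)}
        bad = set(task_raw) - task_known
        if bad:
            raise ValueError(f"unknown task key(s): {sorted(bad)}")
        raw = {**raw, "task": TaskConfig(**task_raw)}
    return RunConfig(**raw)


def run_experiment(config: RunConfig, log=print):
    """Orchestrate simulate -> stats -> fit -> compare -> recover.

    Fully deterministic given ``config.seed``.  Writes per-agent trial logs,
    fit tables, the model-comparison table, the recovery table and a JSON
    manifest (config hash, seeds, schema version) under ``output_dir``.
    Returns the output directory path.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    say = log if config.verbosity else (lambda *_: None)

    cohort_spec = CohortSpec(n_agents=config.n_agents, task=config.task, seed=config.seed)
    say(f"[simulate] {config.n_agents} agents, {config.task.n_trials} trials each")
    cohort = simulate_cohort(cohort_spec)
    if "simulate" in config.stages:
        for rec in cohort:
            write_trial_log(rec.trials, rec.ratings, out / f"agent_{rec.agent_index:02d}")

    if "stats" in config.stages:
        subjects = [(r.trials, r.ratings) for r in cohort]
        rows = []
        for cond in ("reward_level", "collision"):
            split = condition_split_test(subjects, cond)
            rows.append(
                {
                    "condition": cond,
                    **{f"mean_{k}": v for k, v in split.group_mean.items()},
                    "z": split.z,
                    "p_value": split.p_value,
                    "n_subjects": split.n_subjects,
                }
            )
            say(f"[stats] {cond}: means {split.group_mean}, z={split.z:.2f}")
        pd.DataFrame(rows).to_csv(out / "condition_splits.csv", index=False)

    fits_by_model = {}
    if {"fit", "compare"} & set(config.stages):
        for name in config.models:
            spec = CANONICAL_MODELS[name]
            fits = []
            for rec in cohort:
                regs = build_regressors(rec.trials, rec.ratings)
                fits.append(fit_model(rec.ratings, regs, spec, restarts=config.restarts))
            fits_by_model[name] = fits
            say(f"[fit] {name}: mean r2 = {np.mean([f.r_squared for f in fits]):.3f}")
        rows = []
        for name, fits in fits_by_model.items():
            for i, f in enumerate(fits):
                rows.append(
                    {
                        "model": name,
                        "agent": i,
                        **{
                            k: getattr(f.params, k)
                            for k in (
                                "w0",
                                "w_reward",
                                "w_performance",
                                "gamma",
                                "gamma_reward",
                                "gamma_performance",
                                "sigma",
                            )
                            if getattr(f.params, k) is not None
                        },
                        "rss": f.rss,
                        "r_squared": f.r_squared,
                        "n_ratings": f.n_ratings,
                        "bic": f.bic,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)

    if "compare" in config.stages and fits_by_model:
        comparison = compare_models(fits_by_model)
        comparison.table.to_csv(out / "model_comparison.csv")
        say(f"[compare] winner by summed BIC: {comparison.winner}")

    if "recover" in config.stages:
        spec = CANONICAL_MODELS["reward_performance"]
        rec_cohort = simulate_cohort(
            CohortSpec(n_agents=config.n_agents, task=config.task, seed=config.seed + 1),
            spec,
        )
        result = parameter_recovery(rec_cohort, spec, restarts=config.restarts)
        pd.DataFrame(
            {"parameter": list(result.spearman), "spearman_rho": list(result.spearman.values())}
        ).to_csv(out / "recovery.csv", index=False)
        say(f"[recover] Spearman rho: {result.spearman}")

    config_dict = dataclasses.asdict(config)
    # hash only the keys that determine the computation, not where it lands
    hashed = {k: v for k, v in config_dict.items() if k not in ("output_dir", "verbosity")}
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "agent_seeds": [r.seed for r in cohort],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
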