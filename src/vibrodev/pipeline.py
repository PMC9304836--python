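"""End-to-end pipeline: simulate or replay → score → QC → fit → correlate.

Every run writes a manifest recording the configuration snapshot, the seed,
per-stage row counts and a SHA-256 digest of every output file, so a run
can be verified to reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import cohort_to_frame, sample_cohort
from .config import PipelineConfig, load_config
from .correlations import correlation_matrix, ratio_trend_table
from .curves import DISCRIMINATION_TASKS, MEASURES
from .qc import QCResult, apply_qc
from .scoring import batteries_to_table
from .staircase import (
    BatteryResult,
    TASK_ORDER,
    default_task_specs,
    read_trial_log,
    run_battery,
    update_staircase,
    write_trial_log,
)
from .trajectories import (
    fit_exponential2,
    fit_polynomial_incremental,
    fit_power,
    select_best,
)

__all__ = ["RunManifest", "run_pipeline", "validate_trial_log", "fit_trajectories"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    version: str
    mode: str
    row_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, dict] = field(default_factory=dict)

    def register(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": path.name, "sha256": digest}

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "mode": self.mode,
            "row_counts": self.row_counts,
            "outputs": self.outputs,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def fit_trajectories(
    table: pd.DataFrame, config: PipelineConfig | None = None, seed: int = 0
) -> dict[str, dict]:
    """Fit the candidate model families to each outcome measure.

    For every measure with enough included observations, fits the
    incremental polynomial, power and two-term exponential families, selects
    the best by RMSE/R²/SSE and returns a JSON-ready report.
    """
    config = config or PipelineConfig()
    report: dict[str, dict] = {}
    for measure in MEASURES:
        sub = table[["age", measure]].dropna()
        if len(sub) < 8:
            report[measure] = {"skipped": f"only {len(sub)} observations"}
            continue
        x = sub["age"].to_numpy()
        y = sub[measure].to_numpy()
        candidates = {}
        try:
            candidates["polynomial"] = fit_polynomial_incremental(
                x, y, alpha=config.fitting.poly_alpha
            )
        except ValueError:
            pass
        candidates["power"] = fit_power(x, y, config.fitting, seed=seed)
        candidates["exponential2"] = fit_exponential2(x, y, config.fitting, seed=seed)
        selection = select_best(candidates)
        report[measure] = {
            "chosen": selection.chosen,
            "chosen_family": selection.best.family,
            "candidates": {
                name: {
                    "family": fit.family,
                    "coefficients": fit.coefficients,
                    "sse": fit.sse,
                    "rmse": fit.rmse,
                    "r_squared": fit.r_squared,
                    "n_obs": fit.n_obs,
                    "converged": fit.converged,
                }
                for name, fit in selection.fits.items()
            },
        }
    return report


def run_pipeline(
    config: PipelineConfig | str | Path | None = None,
    outdir: str | Path = "vibrodev_run",
    mode: str = "simulate",
    trial_log: str | Path | None = None,
) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``outdir``.

    ``mode="simulate"`` generates a synthetic cohort and runs the battery;
    ``mode="replay"`` ingests an external trial log instead (the cohort
    stage is skipped).  Outputs: cohort table, trial log, outcome table,
    exclusion report, recruited/included counts, model report, correlation
    matrices, ratio trends, and the manifest.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    if mode not in ("simulate", "replay"):
        raise ValueError(f"unknown mode {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.effective_seed

    manifest = RunManifest(
        config=config.model_dump(mode="json"),
        seed=seed,
        version=__version__,
        mode=mode,
    )

    if mode == "simulate":
        observers = sample_cohort(
            config.cohort,
            config.observer,
            seed=seed,
            noise_multiplier=config.effective_noise_multiplier,
        )
        cohort_frame = cohort_to_frame(observers)
        cohort_path = outdir / "cohort.csv"
        cohort_frame.to_csv(cohort_path, index=False)
        manifest.row_counts["cohort"] = len(cohort_frame)
        manifest.register("cohort", cohort_path)

        batteries = [run_battery(obs, seed=seed) for obs in observers]
        log_path = outdir / "trial_log.csv"
        log_frame = write_trial_log(batteries, log_path)
        manifest.row_counts["trial_log"] = len(log_frame)
        manifest.register("trial_log", log_path)
    else:
        if trial_log is None:
            raise ValueError("replay mode requires a trial log file")
        batteries = read_trial_log(trial_log)
        manifest.row_counts["replayed_observers"] = len(batteries)

    outcomes = batteries_to_table(batteries)
    outcomes_path = outdir / "outcomes.csv"
    outcomes.to_csv(outcomes_path, index=False)
    manifest.row_counts["outcomes"] = len(outcomes)
    manifest.register("outcomes", outcomes_path)

    qc_result = apply_qc(batteries, config.qc, outcomes=outcomes)
    exclusions_path = outdir / "exclusions.csv"
    qc_result.report.to_csv(exclusions_path, index=False)
    manifest.register("exclusions", exclusions_path)
    included_path = outdir / "included_outcomes.csv"
    qc_result.included_table.to_csv(included_path, index=False)
    manifest.register("included_outcomes", included_path)
    counts_path = outdir / "group_counts.csv"
    qc_result.counts.to_csv(counts_path, index=False)
    manifest.register("group_counts", counts_path)
    manifest.row_counts["included_rows"] = int(
        qc_result.included_table[list(MEASURES)].notna().any(axis=1).sum()
    )

    model_report = fit_trajectories(qc_result.included_table, config, seed=seed)
    models_path = outdir / "model_report.json"
    models_path.write_text(json.dumps(model_report, indent=2, sort_keys=True))
    manifest.register("model_report", models_path)

    for subgroup, stem in (("adult", "correlations_adult"), ("under-18", "correlations_under18")):
        matrix = correlation_matrix(qc_result.included_table, subgroup)
        path_r = outdir / f"{stem}_r.csv"
        matrix.r.to_csv(path_r)
        manifest.register(f"{stem}_r", path_r)
        path_p = outdir / f"{stem}_p.csv"
        matrix.p.to_csv(path_p)
        manifest.register(f"{stem}_p", path_p)

    trends = ratio_trend_table(qc_result.included_table)
    trends_path = outdir / "ratio_trends.csv"
    trends.to_csv(trends_path, index=False)
    manifest.register("ratio_trends", trends_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def validate_trial_log(path: str | Path) -> pd.DataFrame:
    """Validate an external trial log; returns a table of findings.

    Checks the column dictionary, task names, per-task scored trial counts
    (10 for RT, 20 for discrimination tasks), finger labels, positive RT
    latencies, and staircase consistency: every consecutive pair of tracked
    values must be one staircase update apart (or bound-clamped).  An empty
    result means a clean log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    specs = default_task_specs()
    findings: list[dict] = []

    from .staircase import TRIAL_LOG_COLUMNS

    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        return pd.DataFrame(
            [{"observer_id": pd.NA, "task": pd.NA, "row": pd.NA,
              "issue": f"missing columns {missing}"}]
        )

    scored = frame[~frame["is_practice"].astype(bool)]
    for (observer_id, task), rows in scored.groupby(["observer_id", "task"]):
        if task not in specs:
            findings.append(
                {"observer_id": observer_id, "task": task, "row": int(rows.index[0]),
                 "issue": f"unknown task {task!r}"}
            )
            continue
        spec = specs[task]
        rows = rows.sort_values("trial_index")
        if len(rows) != spec.n_trials:
            findings.append(
                {"observer_id": observer_id, "task": task, "row": int(rows.index[0]),
                 "issue": f"incomplete: {len(rows)} of {spec.n_trials} trials"}
            )
        bad_fingers = ~rows["response_finger"].isin(["index", "middle"])
        for idx in rows.index[bad_fingers]:
            findings.append(
                {"observer_id": observer_id, "task": task, "row": int(idx),
                 "issue": "invalid response finger"}
            )
        if spec.is_discrimination:
            values = rows["tracked_value"].to_numpy(dtype=float)
            correct = rows["correct"].to_numpy(dtype=bool)
            for k in range(len(values) - 1):
                expected = update_staircase(values[k], correct[k], spec)
                if not math.isclose(values[k + 1], expected, rel_tol=1e-6, abs_tol=1e-6):
                    findings.append(
                        {"observer_id": observer_id, "task": task,
                         "row": int(rows.index[k + 1]),
                         "issue": (
                             f"staircase inconsistency: value {values[k+1]:g} after "
                             f"{'correct' if correct[k] else 'incorrect'} trial at "
                             f"{values[k]:g} (expected {expected:g})"
                         )}
                    )
        else:
            bad_latency = ~(rows["latency_ms"] > 0)
            for idx in rows.index[bad_latency]:
                findings.append(
                    {"observer_id": observer_id, "task": task, "row": int(idx),
                     "issue": "non-positive latency"}
                )
    return pd.DataFrame(findings, columns=["observer_id", "task", "row", "issue"])
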