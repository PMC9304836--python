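"""Per-task outcome measures.

The battery yields six outcomes per observer:

* ``RT`` — mean of the median six of ten reaction-time trials (the two
  fastest and the two slowest are discarded), in ms.
* ``RTVar`` — sample standard deviation (n−1) of the same six trials.
* ``sqAD``, ``smAD`` — amplitude discrimination thresholds: the mean tracked
  amplitude difference over scored trials 16–20, in μm.
* ``TOJ`` — mean inter-stimulus interval over trials 16–20, in ms.
* ``DD`` — mean duration difference over trials 16–20, in ms.

Thresholds are only computed from complete 20-trial staircases; partial
traces yield a missing result, never a partial threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import age_band
from .curves import DISCRIMINATION_TASKS, MEASURES
from .staircase import BatteryResult, StaircaseTrace

__all__ = [
    "IncompleteTraceError",
    "TaskResult",
    "rt_summary",
    "discrimination_threshold",
    "score_battery",
    "batteries_to_table",
    "write_outcomes",
]

RT_TRIALS = 10
RT_TRIM = 2  # trials dropped from each end
THRESHOLD_TRIALS = 5  # "final five" scored trials


class IncompleteTraceError(ValueError):
    """Raised when a threshold is requested from an incomplete trace."""


@dataclass(frozen=True)
class TaskResult:
    """One outcome for one observer; missing outcomes carry NaN."""

    observer_id: int
    task: str
    outcome: float
    outcome_kind: str  # rt_mean | rt_variability | threshold
    n_trials_used: int
    qc_flags: frozenset = frozenset()


def rt_summary(latencies: Sequence[float]) -> dict[str, float]:
    """Trimmed reaction-time statistics from exactly 10 trials.

    Sorts the latencies, drops the two fastest and the two slowest, and
    returns the arithmetic mean and the sample (n−1) standard deviation of
    the median six.
    """
    arr = np.asarray(latencies, dtype=float)
    if arr.shape != (RT_TRIALS,):
        raise ValueError(f"rt_summary expects exactly {RT_TRIALS} latencies")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("latencies must be finite and positive")
    middle = np.sort(arr)[RT_TRIM : RT_TRIALS - RT_TRIM]
    return {
        "rt_mean": float(np.mean(middle)),
        "rt_variability": float(np.std(middle, ddof=1)),
    }


def discrimination_threshold(trace: StaircaseTrace) -> float:
    """Mean tracked value over the final five of 20 scored trials."""
    if not trace.completed or len(trace.trials) != 20:
        raise IncompleteTraceError(
            f"{trace.task} trace for observer {trace.observer_id} is incomplete "
            f"({trace.failure_reason}, {len(trace.trials)} trials)"
        )
    return float(np.mean(trace.tracked_values[-THRESHOLD_TRIALS:]))


def score_battery(battery: BatteryResult) -> list[TaskResult]:
    """Score all six outcomes; failed tasks yield NaN results with a flag."""
    results: list[TaskResult] = []

    rt_trace = battery.traces.get("RT")
    if rt_trace is not None and rt_trace.completed and len(rt_trace.trials) == RT_TRIALS:
        summary = rt_summary(rt_trace.latencies)
        results.append(
            TaskResult(battery.observer_id, "RT", summary["rt_mean"], "rt_mean", 6)
        )
        results.append(
            TaskResult(
                battery.observer_id,
                "RTVar",
                summary["rt_variability"],
                "rt_variability",
                6,
            )
        )
    else:
        reason = rt_trace.failure_reason if rt_trace is not None else "missing"
        for measure, kind in (("RT", "rt_mean"), ("RTVar", "rt_variability")):
            results.append(
                TaskResult(
                    battery.observer_id,
                    measure,
                    math.nan,
                    kind,
                    0,
                    frozenset({reason}),
                )
            )

    for task in DISCRIMINATION_TASKS:
        trace = battery.traces.get(task)
        try:
            if trace is None:
                raise IncompleteTraceError("missing")
            value = discrimination_threshold(trace)
            results.append(
                TaskResult(battery.observer_id, task, value, "threshold", THRESHOLD_TRIALS)
            )
        except IncompleteTraceError:
            reason = trace.failure_reason if trace is not None else "missing"
            results.append(
                TaskResult(
                    battery.observer_id, task, math.nan, "threshold", 0, frozenset({reason})
                )
            )
    return results


def batteries_to_table(batteries: Iterable[BatteryResult]) -> pd.DataFrame:
    """Wide per-observer outcome table (one column per measure).

    Columns: ``observer_id``, ``age``, ``age_band`` and the six outcome
    measures; missing outcomes are NaN.
    """
    rows = []
    for battery in batteries:
        row: dict[str, object] = {
            "observer_id": battery.observer_id,
            "age": battery.age,
            "age_band": age_band(battery.age),
        }
        for result in score_battery(battery):
            row[result.task] = result.outcome
        rows.append(row)
    columns = ["observer_id", "age", "age_band", *MEASURES]
    return pd.DataFrame(rows, columns=columns)


def write_outcomes(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-observer outcome table as delimiter-separated text."""
    table.to_csv(path, index=False)
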