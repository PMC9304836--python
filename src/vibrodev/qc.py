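"""Objective quality-control rules and the included-participant table.

Two rules decide which task results enter the developmental analysis:

1. **Compliance (switch) rule** — a discrimination task is excluded when the
   participant's response finger switched fewer than 3 times across the 20
   scored trials (a one-finger perseverator has not understood the task).
2. **Group outlier rule** — within each recruitment band, an outcome more
   than 3 standard deviations from the band mean is excluded.  The mean and
   SD are computed once, from all compliant complete values in that band and
   task (a single, non-iterative pass); a value at exactly 3 SD is kept.

Reaction-time variability (RTVar) is derived from the RT trials, so an RT
exclusion removes RTVar as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import BAND_ORDER
from .config import QCConfig
from .curves import DISCRIMINATION_TASKS, MEASURES
from .scoring import batteries_to_table
from .staircase import BatteryResult, StaircaseTrace

__all__ = [
    "switch_count",
    "compliance_filter",
    "outlier_filter",
    "flag_diverging_trace",
    "build_included_table",
    "apply_qc",
    "QCResult",
]

STATUS_INCLUDED = "included"
STATUS_SWITCH = "excluded_switch"
STATUS_OUTLIER = "excluded_outlier"
STATUS_INCOMPLETE = "excluded_incomplete"


def switch_count(response_fingers: Sequence[str]) -> int:
    """Number of positions where the response differs from the previous one."""
    if len(response_fingers) < 2:
        raise ValueError("switch_count requires at least two responses")
    return sum(
        1
        for prev, cur in zip(response_fingers, response_fingers[1:])
        if cur != prev
    )


def compliance_filter(
    traces: Iterable[StaircaseTrace], min_switches: int = 3
) -> pd.DataFrame:
    """Apply the switch rule to discrimination-task traces.

    Returns one row per trace: observer_id, task, switch_count, status.
    Incomplete traces are marked ``excluded_incomplete``; the switch rule
    itself never applies to the RT task.
    """
    rows = []
    for trace in traces:
        if trace.task not in DISCRIMINATION_TASKS:
            raise ValueError(f"switch rule applies to discrimination tasks, not {trace.task}")
        if not trace.completed:
            rows.append(
                {
                    "observer_id": trace.observer_id,
                    "task": trace.task,
                    "switch_count": pd.NA,
                    "status": STATUS_INCOMPLETE,
                }
            )
            continue
        n_switch = switch_count(trace.response_fingers)
        status = STATUS_INCLUDED if n_switch >= min_switches else STATUS_SWITCH
        rows.append(
            {
                "observer_id": trace.observer_id,
                "task": trace.task,
                "switch_count": n_switch,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows, columns=["observer_id", "task", "switch_count", "status"]
    )


def outlier_filter(
    values: Sequence[float],
    group_labels: Sequence[str],
    sd_limit: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Single-pass group-wise outlier rule.

    For each group, the mean and SD are computed once from all finite values;
    a value is excluded iff ``|value - mean| > sd_limit * sd`` (strictly
    greater, so a value at exactly the limit is kept).  Groups with fewer
    than two finite values are skipped and flagged in the stats table.

    Returns ``(excluded, stats)`` where ``excluded`` is a boolean array
    aligned with ``values`` and ``stats`` has one row per group.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    excluded = np.zeros(len(values), dtype=bool)
    stats_rows = []
    for group in pd.unique(group_labels):
        mask = (group_labels == group) & np.isfinite(values)
        n = int(mask.sum())
        if n < 2:
            stats_rows.append(
                {"group": group, "n": n, "mean": math.nan, "sd": math.nan, "applied": False}
            )
            continue
        mean = float(values[mask].mean())
        sd = float(values[mask].std(ddof=1))
        excluded[mask] = np.abs(values[mask] - mean) > sd_limit * sd
        stats_rows.append(
            {"group": group, "n": n, "mean": mean, "sd": sd, "applied": True}
        )
    return excluded, pd.DataFrame(stats_rows)


def flag_diverging_trace(trace: StaircaseTrace, window: int = 10) -> bool:
    """Heuristic trace-quality flag (disabled by default in the pipeline).

    Flags a completed staircase whose tracked value trends *away* from
    convergence over the final ``window`` trials (positive slope larger than
    half a mean step).  This is an objective stand-in for a by-eye review of
    staircase profiles and is clearly not part of the two canonical rules.
    """
    if not trace.completed or len(trace.trials) < window:
        return False
    tail = trace.tracked_values[-window:]
    slope = float(np.polyfit(np.arange(window), tail, 1)[0])
    typical_step = float(np.mean(np.abs(np.diff(tail)))) or 1.0
    return slope > 0.5 * typical_step


@dataclass
class QCResult:
    """Exclusion report, included outcome table, and recruited/included counts."""

    report: pd.DataFrame  # observer_id, task, status, switch_count
    included_table: pd.DataFrame  # wide outcomes with exclusions set to NaN
    counts: pd.DataFrame  # band x measure recruited/included table


def _trace_for_measure(battery: BatteryResult, measure: str) -> StaircaseTrace | None:
    # RTVar is computed from the RT trials
    return battery.traces.get("RT" if measure == "RTVar" else measure)


def apply_qc(
    batteries: Sequence[BatteryResult],
    config: QCConfig | None = None,
    outcomes: pd.DataFrame | None = None,
) -> QCResult:
    """Run the full QC pipeline over a cohort of battery results."""
    config = config or QCConfig()
    if outcomes is None:
        outcomes = batteries_to_table(batteries)
    outcomes = outcomes.set_index("observer_id", drop=False)

    rows = []
    for battery in batteries:
        for measure in MEASURES:
            trace = _trace_for_measure(battery, measure)
            outcome = outcomes.at[battery.observer_id, measure]
            n_switch: object = pd.NA
            if trace is None or not trace.completed or not math.isfinite(outcome):
                status = STATUS_INCOMPLETE
            elif measure in DISCRIMINATION_TASKS:
                n_switch = switch_count(trace.response_fingers)
                if n_switch < config.min_switches:
                    status = STATUS_SWITCH
                elif config.flag_diverging_traces and flag_diverging_trace(trace):
                    status = STATUS_SWITCH
                else:
                    status = STATUS_INCLUDED
            else:
                status = STATUS_INCLUDED
            rows.append(
                {
                    "observer_id": battery.observer_id,
                    "age_band": outcomes.at[battery.observer_id, "age_band"],
                    "task": measure,
                    "switch_count": n_switch,
                    "status": status,
                }
            )
    report = pd.DataFrame(rows)

    # group-wise outlier pass over the values that survived the earlier rules
    outlier_measures = (
        MEASURES if config.outlier_scope == "all" else ("RT", "RTVar")
    )
    for measure in outlier_measures:
        mask = (report["task"] == measure) & (report["status"] == STATUS_INCLUDED)
        sub = report[mask]
        if sub.empty:
            continue
        values = outcomes.loc[sub["observer_id"], measure].to_numpy(dtype=float)
        bands = sub["age_band"].to_numpy()
        excluded, _ = outlier_filter(values, bands, config.sd_limit)
        report.loc[sub.index[excluded], "status"] = STATUS_OUTLIER

    # RTVar inherits an RT outlier exclusion (same underlying trials)
    rt_excluded = report[
        (report["task"] == "RT") & (report["status"] == STATUS_OUTLIER)
    ]["observer_id"]
    inherit = (
        report["task"].eq("RTVar")
        & report["observer_id"].isin(rt_excluded)
        & report["status"].eq(STATUS_INCLUDED)
    )
    report.loc[inherit, "status"] = STATUS_OUTLIER

    return build_included_table(outcomes.reset_index(drop=True), report)


def build_included_table(
    outcomes: pd.DataFrame, report: pd.DataFrame
) -> QCResult:
    """Assemble the included-outcome table and recruited/included counts."""
    included = outcomes.copy()
    for measure in MEASURES:
        bad = report[
            (report["task"] == measure) & (report["status"] != STATUS_INCLUDED)
        ]["observer_id"]
        included.loc[included["observer_id"].isin(bad), measure] = math.nan

    count_rows = []
    for band in BAND_ORDER:
        in_band = outcomes["age_band"] == band
        recruited = int(in_band.sum())
        row: dict[str, object] = {"age_band": band, "recruited": recruited}
        for measure in MEASURES:
            band_report = report[
                (report["task"] == measure) & (report["age_band"] == band)
            ]
            row[measure] = int((band_report["status"] == STATUS_INCLUDED).sum())
        count_rows.append(row)
    counts = pd.DataFrame(count_rows, columns=["age_band", "recruited", *MEASURES])
    return QCResult(report=report, included_table=included, counts=counts)


def write_exclusion_report(result: QCResult, path: str | Path) -> None:
    """Write the tidy exclusion report as delimiter-separated text."""
    result.report.to_csv(path, index=False)
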