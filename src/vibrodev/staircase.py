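"""The five-task vibrotactile battery and its adaptive staircases.

The battery comprises, in fixed order: a reaction-time (RT) task and four
two-alternative forced-choice discrimination tasks — sequential and
simultaneous amplitude discrimination (sqAD, smAD), temporal order judgment
(TOJ) and duration discrimination (DD).  Each discrimination task runs a
1-up/1-down staircase on a tracked stimulus parameter: the amplitude
difference (additive ±20 μm steps), the inter-stimulus interval
(multiplicative ±15% steps) or the duration difference (additive ±25 ms
steps).  Every task is preceded by practice trials that must yield three
consecutive correct responses before the scored trials begin.

Stimulus delivery alternates pseudo-randomly between the index and middle
finger (balanced shuffled blocks of two, so each finger carries the correct
answer equally often).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .cohort import ObserverProfile, _p_correct, respond, sample_rt
from .curves import DISCRIMINATION_TASKS

__all__ = [
    "StepRule",
    "TaskSpec",
    "TrialRecord",
    "StaircaseTrace",
    "BatteryResult",
    "TASK_ORDER",
    "FINGERS",
    "default_task_specs",
    "update_staircase",
    "run_practice",
    "run_staircase",
    "run_rt_task",
    "run_battery",
    "simulate_trace_from_flags",
    "write_trial_log",
    "read_trial_log",
]

TASK_ORDER = ("RT", "sqAD", "smAD", "TOJ", "DD")
FINGERS = ("index", "middle")

#: practice attempts allowed before declaring the gate failed
PRACTICE_ATTEMPT_BUDGET = 15
PRACTICE_REQUIRED_STREAK = 3


@dataclass(frozen=True)
class StepRule:
    """Staircase update: ``additive`` (± step) or ``multiplicative`` (× 1∓f)."""

    kind: str  # "additive" | "multiplicative"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown step rule {self.kind!r}")
        if self.kind == "additive" and self.value <= 0:
            raise ValueError("additive step must be > 0")
        if self.kind == "multiplicative" and not (0 < self.value < 1):
            raise ValueError("multiplicative fraction must lie in (0, 1)")


@dataclass(frozen=True)
class TaskSpec:
    """Stimulus and staircase parameters of one battery task."""

    name: str
    stimulus_frequency: float  # Hz
    standard_amplitude: float  # μm
    n_trials: int
    iti_range: tuple[float, float]  # ms
    stimulus_duration: Optional[float] = None  # ms
    standard_duration: Optional[float] = None  # ms
    comparison_start: Optional[float] = None  # μm or ms
    isi: Optional[float] = None  # ms
    step_rule: Optional[StepRule] = None
    tracked_parameter: str = "none"  # amplitude_difference | isi | duration_difference | none
    start_value: Optional[float] = None  # tracked units
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tracked_parameter != "none":
            if self.step_rule is None or self.start_value is None:
                raise ValueError(f"{self.name}: tracked task needs step rule and start value")
            if self.lower_bound is None or self.upper_bound is None:
                raise ValueError(f"{self.name}: tracked task needs bounds")
            if not (self.lower_bound <= self.start_value <= self.upper_bound):
                raise ValueError(f"{self.name}: start value outside bounds")
            if self.step_rule.kind == "multiplicative" and self.lower_bound <= 0:
                raise ValueError(f"{self.name}: multiplicative staircase needs lower bound > 0")

    @property
    def is_discrimination(self) -> bool:
        return self.tracked_parameter != "none"


def default_task_specs() -> dict[str, TaskSpec]:
    """The five battery tasks with their standard parameters.

    RT: 25 Hz, 300 μm, 40 ms pulses, 10 trials, ITI 4000–7000 ms.
    sqAD/smAD: 25 Hz, 500 ms stimuli, standard 200 μm, comparison starting at
    400 μm, ±20 μm steps, 20 trials (sqAD sequential with 500 ms ISI, smAD
    simultaneous).  TOJ: 25 Hz, 300 μm, 40 ms pulses, starting ISI 150 ms,
    ±15% steps.  DD: 40 Hz, 300 μm, standard 500 ms vs comparison starting at
    750 ms, ±25 ms steps.

    Tracked differences are clamped to one step size at the bottom (so the
    comparison never equals the standard; TOJ floors at 1 ms) and to twice
    the starting difference at the top (TOJ: 500 ms ISI).
    """
    return {
        "RT": TaskSpec(
            name="RT",
            stimulus_frequency=25.0,
            standard_amplitude=300.0,
            stimulus_duration=40.0,
            n_trials=10,
            iti_range=(4000.0, 7000.0),
        ),
        "sqAD": TaskSpec(
            name="sqAD",
            stimulus_frequency=25.0,
            standard_amplitude=200.0,
            comparison_start=400.0,
            stimulus_duration=500.0,
            isi=500.0,
            n_trials=20,
            iti_range=(5000.0, 5000.0),
            step_rule=StepRule("additive", 20.0),
            tracked_parameter="amplitude_difference",
            start_value=200.0,
            lower_bound=20.0,
            upper_bound=400.0,
        ),
        "smAD": TaskSpec(
            name="smAD",
            stimulus_frequency=25.0,
            standard_amplitude=200.0,
            comparison_start=400.0,
            stimulus_duration=500.0,
            isi=0.0,
            n_trials=20,
            iti_range=(5000.0, 5000.0),
            step_rule=StepRule("additive", 20.0),
            tracked_parameter="amplitude_difference",
            start_value=200.0,
            lower_bound=20.0,
            upper_bound=400.0,
        ),
        "TOJ": TaskSpec(
            name="TOJ",
            stimulus_frequency=25.0,
            standard_amplitude=300.0,
            stimulus_duration=40.0,
            n_trials=20,
            iti_range=(5000.0, 5000.0),
            step_rule=StepRule("multiplicative", 0.15),
            tracked_parameter="isi",
            start_value=150.0,
            lower_bound=1.0,
            upper_bound=500.0,
        ),
        "DD": TaskSpec(
            name="DD",
            stimulus_frequency=40.0,
            standard_amplitude=300.0,
            standard_duration=500.0,
            comparison_start=750.0,
            isi=500.0,
            n_trials=20,
            iti_range=(5000.0, 5000.0),
            step_rule=StepRule("additive", 25.0),
            tracked_parameter="duration_difference",
            start_value=250.0,
            lower_bound=25.0,
            upper_bound=500.0,
        ),
    }


def update_staircase(current: float, correct: bool, spec: TaskSpec) -> float:
    """One 1-up/1-down update of the tracked value, clamped to the bounds."""
    rule = spec.step_rule
    if rule is None:
        raise ValueError(f"{spec.name} has no staircase")
    if rule.kind == "additive":
        nxt = current - rule.value if correct else current + rule.value
    else:
        nxt = current * (1.0 - rule.value if correct else 1.0 + rule.value)
    return float(min(max(nxt, spec.lower_bound), spec.upper_bound))


@dataclass(frozen=True)
class TrialRecord:
    """One scored (or practice) trial."""

    trial_index: int  # 1-based
    tracked_value: float  # μm or ms; NaN for RT trials
    assigned_finger: str
    response_finger: str
    correct: bool
    latency_ms: float  # NaN except RT
    iti_ms: float
    is_practice: bool = False


@dataclass
class StaircaseTrace:
    """The ordered trials of one task run for one observer."""

    task: str
    observer_id: int
    trials: list[TrialRecord] = field(default_factory=list)
    completed: bool = False
    failure_reason: str = "none"  # none | failed_practice | aborted
    practice_attempts: int = 0

    @property
    def tracked_values(self) -> np.ndarray:
        return np.array([t.tracked_value for t in self.trials])

    @property
    def response_fingers(self) -> list[str]:
        return [t.response_finger for t in self.trials]

    @property
    def latencies(self) -> np.ndarray:
        return np.array([t.latency_ms for t in self.trials])


@dataclass
class BatteryResult:
    """Five task traces for one observer, in fixed battery order."""

    observer_id: int
    age: float
    traces: dict[str, StaircaseTrace]
    seed: int = 0
    observer: Optional[ObserverProfile] = None


def _finger_schedule(n: int, rng: np.random.Generator) -> list[str]:
    # balanced blocks of two: within each consecutive pair both fingers occur
    schedule: list[str] = []
    while len(schedule) < n:
        pair = list(FINGERS)
        rng.shuffle(pair)
        schedule.extend(pair)
    return schedule[:n]


def run_practice(
    observer: ObserverProfile,
    spec: TaskSpec,
    rng: np.random.Generator,
    max_attempts: int = PRACTICE_ATTEMPT_BUDGET,
) -> tuple[bool, int]:
    """Run the practice gate: three consecutive correct responses.

    Each practice response is gated by the observer's comprehension
    probability for the task; a non-comprehending response is incorrect.
    Practice uses the staircase start value (RT practice only requires a
    response, so the psychometric factor is 1).  Returns
    ``(passed, attempts_used)``.
    """
    comprehension = observer.comprehension.get(spec.name, 1.0)
    if spec.is_discrimination:
        p = comprehension * _p_correct(observer, spec.name, spec.start_value)
    else:
        p = comprehension
    streak = 0
    for attempt in range(1, max_attempts + 1):
        if rng.random() < p:
            streak += 1
        else:
            streak = 0
        if streak >= PRACTICE_REQUIRED_STREAK:
            return True, attempt
    return False, max_attempts


def run_staircase(
    observer: ObserverProfile,
    spec: TaskSpec,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> StaircaseTrace:
    """Run practice plus the full 20-trial staircase for one task."""
    if not spec.is_discrimination:
        raise ValueError(f"{spec.name} is not a staircase task; use run_rt_task")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trace = StaircaseTrace(task=spec.name, observer_id=observer.observer_id)
    passed, attempts = run_practice(observer, spec, rng)
    trace.practice_attempts = attempts
    if not passed:
        trace.failure_reason = "failed_practice"
        return trace

    fingers = _finger_schedule(spec.n_trials, rng)
    value = float(spec.start_value)
    for i in range(1, spec.n_trials + 1):
        assigned = fingers[i - 1]
        correct, chosen = respond(observer, spec.name, value, assigned, rng)
        iti = float(rng.uniform(*spec.iti_range))
        trace.trials.append(
            TrialRecord(
                trial_index=i,
                tracked_value=value,
                assigned_finger=assigned,
                response_finger=chosen,
                correct=correct,
                latency_ms=math.nan,
                iti_ms=iti,
            )
        )
        value = update_staircase(value, correct, spec)
    trace.completed = True
    return trace


def run_rt_task(
    observer: ObserverProfile,
    spec: TaskSpec,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> StaircaseTrace:
    """Run practice plus the 10-trial reaction-time task."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trace = StaircaseTrace(task=spec.name, observer_id=observer.observer_id)
    passed, attempts = run_practice(observer, spec, rng)
    trace.practice_attempts = attempts
    if not passed:
        trace.failure_reason = "failed_practice"
        return trace
    fingers = _finger_schedule(spec.n_trials, rng)
    for i in range(1, spec.n_trials + 1):
        latency = float(sample_rt(observer, rng))
        iti = float(rng.uniform(*spec.iti_range))
        trace.trials.append(
            TrialRecord(
                trial_index=i,
                tracked_value=math.nan,
                assigned_finger=fingers[i - 1],
                response_finger=fingers[i - 1],
                correct=True,
                latency_ms=latency,
                iti_ms=iti,
            )
        )
    trace.completed = True
    return trace


def run_battery(
    observer: ObserverProfile,
    seed: int = 0,
    specs: dict[str, TaskSpec] | None = None,
) -> BatteryResult:
    """Run the five tasks in fixed order (RT, sqAD, smAD, TOJ, DD).

    Each task uses an independent substream keyed by
    ``(seed, observer_id, task_index)``, so traces are reproducible and
    insensitive to the composition of the rest of the cohort.
    """
    specs = specs or default_task_specs()
    traces: dict[str, StaircaseTrace] = {}
    for idx, task in enumerate(TASK_ORDER):
        spec = specs[task]
        rng = np.random.default_rng([seed, observer.observer_id, idx])
        if spec.is_discrimination:
            traces[task] = run_staircase(observer, spec, rng)
        else:
            traces[task] = run_rt_task(observer, spec, rng)
    return BatteryResult(
        observer_id=observer.observer_id,
        age=observer.age,
        traces=traces,
        seed=seed,
        observer=observer,
    )


def simulate_trace_from_flags(
    flags: Sequence[bool], spec: TaskSpec, observer_id: int = 0
) -> StaircaseTrace:
    """Build a deterministic trace by replaying a correctness sequence.

    Useful for closed-form checks and for validating external trial logs:
    the tracked-value sequence is exactly what the staircase rule produces
    for the given flags.
    """
    trace = StaircaseTrace(task=spec.name, observer_id=observer_id)
    value = float(spec.start_value)
    for i, correct in enumerate(flags, start=1):
        assigned = FINGERS[(i - 1) % 2]
        trace.trials.append(
            TrialRecord(
                trial_index=i,
                tracked_value=value,
                assigned_finger=assigned,
                response_finger=assigned if correct else FINGERS[i % 2],
                correct=bool(correct),
                latency_ms=math.nan,
                iti_ms=float(np.mean(spec.iti_range)),
            )
        )
        value = update_staircase(value, bool(correct), spec)
    trace.completed = len(flags) == spec.n_trials
    return trace


# ---------------------------------------------------------------------------
# trial-log IO (also the ingestion format for replaying real data)

TRIAL_LOG_COLUMNS = [
    "observer_id",
    "age",
    "task",
    "trial_index",
    "is_practice",
    "tracked_value",
    "assigned_finger",
    "response_finger",
    "correct",
    "latency_ms",
    "iti_ms",
    "seed",
]


def write_trial_log(batteries: Iterable[BatteryResult], path: str | Path) -> pd.DataFrame:
    """Write one row per scored trial in delimiter-separated text."""
    rows = []
    for battery in batteries:
        for task in TASK_ORDER:
            trace = battery.traces.get(task)
            if trace is None:
                continue
            for trial in trace.trials:
                rows.append(
                    {
                        "observer_id": battery.observer_id,
                        "age": battery.age,
                        "task": task,
                        "trial_index": trial.trial_index,
                        "is_practice": trial.is_practice,
                        "tracked_value": trial.tracked_value,
                        "assigned_finger": trial.assigned_finger,
                        "response_finger": trial.response_finger,
                        "correct": trial.correct,
                        "latency_ms": trial.latency_ms,
                        "iti_ms": trial.iti_ms,
                        "seed": battery.seed,
                    }
                )
    frame = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
    frame.to_csv(path, index=False)
    return frame


def read_trial_log(
    path: str | Path, specs: dict[str, TaskSpec] | None = None
) -> list[BatteryResult]:
    """Read a trial log back into per-observer battery results.

    Practice rows (``is_practice`` true) are ignored; a task block is marked
    completed when it holds the full scored trial count for that task.
    """
    specs = specs or default_task_specs()
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial log is missing columns {missing}")
    frame = frame[~frame["is_practice"].astype(bool)]
    batteries: list[BatteryResult] = []
    for observer_id, obs_rows in frame.groupby("observer_id", sort=True):
        age = float(obs_rows["age"].iloc[0])
        traces: dict[str, StaircaseTrace] = {}
        for task, task_rows in obs_rows.groupby("task", sort=False):
            task_rows = task_rows.sort_values("trial_index")
            trace = StaircaseTrace(task=str(task), observer_id=int(observer_id))
            for row in task_rows.itertuples(index=False):
                trace.trials.append(
                    TrialRecord(
                        trial_index=int(row.trial_index),
                        tracked_value=float(row.tracked_value),
                        assigned_finger=str(row.assigned_finger),
                        response_finger=str(row.response_finger),
                        correct=bool(row.correct),
                        latency_ms=float(row.latency_ms),
                        iti_ms=float(row.iti_ms),
                    )
                )
            expected = specs[task].n_trials if task in specs else None
            trace.completed = expected is not None and len(trace.trials) == expected
            if not trace.completed:
                trace.failure_reason = "aborted"
            traces[str(task)] = trace
        seed = int(obs_rows["seed"].iloc[0]) if len(obs_rows) else 0
        batteries.append(
            BatteryResult(
                observer_id=int(observer_id), age=age, traces=traces, seed=seed
            )
        )
    return batteries
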