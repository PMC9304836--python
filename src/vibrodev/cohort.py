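"""Synthetic observers and cohorts.

An :class:`ObserverProfile` is a simulated participant: an age, one true
threshold per discrimination task, a psychometric slope and lapse rate, a
latency distribution for the reaction-time task, and per-task comprehension
probabilities that gate the practice trials.

The observer model
------------------
Discrimination responses follow a two-alternative forced-choice (2AFC)
psychometric function.  For a stimulus difference ``delta`` and true
threshold ``theta``::

    P(correct) = 0.5 + (0.5 - lapse/2) * F(delta)
    F(delta)   = 1 / (1 + (delta/theta) ** (-slope))      (log-logistic)

so ``F(0) = 0`` (chance at zero difference), ``F(theta) = 0.5`` (the true
threshold is the 75%-correct point of the lapse-free curve) and
``F(inf) = 1`` (ceiling ``1 - lapse/2``).  Latencies are lognormal,
parameterized by their median so that trial noise never shifts the median.

Population structure
--------------------
True thresholds are the task's generating curve evaluated at the observer's
age times a unit-median lognormal person effect whose log-SD is
``person_spread * noise_multiplier``.  The simultaneous amplitude threshold
is coupled to the sequential one (``smAD = sqAD * (1 + (factor-1)*L)``,
``L`` lognormal with unit median) so that smAD >= sqAD holds by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CohortSpec, ObserverConfig, PipelineConfig
from .curves import DISCRIMINATION_TASKS, evaluate_curve

__all__ = [
    "AGE_BANDS",
    "BAND_ORDER",
    "ObserverProfile",
    "age_band",
    "psychometric_correct_probability",
    "respond",
    "sample_rt",
    "make_observer",
    "perfect_observer",
    "chance_observer",
    "sample_cohort",
    "cohort_to_frame",
]

#: Recruitment bands as half-open age intervals [lo, hi).
AGE_BANDS: dict[str, tuple[float, float]] = {
    "3-6": (3.0, 7.0),
    "7-12": (7.0, 13.0),
    "13-17": (13.0, 18.0),
    "18-23": (18.0, 24.0),
}

BAND_ORDER = ("3-6", "7-12", "13-17", "18-23")

TASKS = ("RT", "sqAD", "smAD", "TOJ", "DD")


def age_band(age: float) -> str:
    """Return the recruitment-band label containing ``age``."""
    for label, (lo, hi) in AGE_BANDS.items():
        if lo <= age < hi:
            return label
    raise ValueError(f"age {age} outside the recruited range [3, 24)")


@dataclass(frozen=True)
class ObserverProfile:
    """A synthetic participant.

    ``true_thresholds`` maps the four discrimination tasks to their true
    thresholds (μm for sqAD/smAD, ms for TOJ/DD).  ``rt_location`` is a
    latency shift (ms, usually 0), ``rt_scale`` the median latency above the
    shift (ms) and ``rt_shape`` the log-SD of the lognormal latency
    distribution; the latency median is ``rt_location + rt_scale``.
    """

    observer_id: int
    age: float
    true_thresholds: Mapping[str, float]
    psychometric_slope: Mapping[str, float]
    lapse_rate: float
    rt_location: float
    rt_scale: float
    rt_shape: float
    comprehension: Mapping[str, float]

    def __post_init__(self) -> None:
        if not (3.0 <= self.age < 24.0):
            raise ValueError(f"age {self.age} outside [3, 24)")
        for task, theta in self.true_thresholds.items():
            if theta < 0:
                raise ValueError(f"{task} true threshold must be >= 0")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.rt_scale < 0 or self.rt_shape < 0:
            raise ValueError("rt_scale and rt_shape must be >= 0")
        for task, p in self.comprehension.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{task} comprehension must lie in [0, 1]")

    @property
    def band(self) -> str:
        return age_band(self.age)

    @property
    def rt_median(self) -> float:
        return self.rt_location + self.rt_scale


def psychometric_correct_probability(
    threshold: float, slope: float, lapse: float, delta: float
) -> float:
    """2AFC probability of a correct response at stimulus difference ``delta``.

    ``threshold == 0`` denotes a perfect observer (``F = 1`` for any positive
    difference); ``threshold == inf`` a chance-level observer (``F = 0``).
    """
    if delta < 0:
        raise ValueError("stimulus difference must be >= 0")
    if delta == 0 or math.isinf(threshold):
        f = 0.0
    elif threshold == 0:
        f = 1.0
    else:
        f = 1.0 / (1.0 + (delta / threshold) ** (-slope))
    return 0.5 + (0.5 - lapse / 2.0) * f


def _p_correct(observer: ObserverProfile, task: str, delta: float) -> float:
    return psychometric_correct_probability(
        observer.true_thresholds[task],
        observer.psychometric_slope[task],
        observer.lapse_rate,
        delta,
    )


def respond(
    observer: ObserverProfile,
    task: str,
    delta: float,
    assigned_finger: str,
    rng: np.random.Generator,
) -> tuple[bool, str]:
    """Simulate one 2AFC response; returns ``(correct, chosen_finger)``.

    ``assigned_finger`` is the finger carrying the correct answer on this
    trial; an incorrect response chooses the other finger.
    """
    correct = rng.random() < _p_correct(observer, task, delta)
    other = "middle" if assigned_finger == "index" else "index"
    return correct, (assigned_finger if correct else other)


def sample_rt(
    observer: ObserverProfile, rng: np.random.Generator, size: int | None = None
):
    """Draw latency(ies) in ms from the observer's lognormal RT distribution.

    The distribution median is ``rt_location + rt_scale`` for any shape; a
    zero shape is the degenerate (constant) distribution.
    """
    z = rng.standard_normal(size)
    return observer.rt_location + observer.rt_scale * np.exp(
        observer.rt_shape * z
    )


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_observer(
    age: float,
    config: ObserverConfig | None = None,
    seed: int | Sequence[int] | np.random.Generator = 0,
    noise_multiplier: float = 1.0,
    observer_id: int = 0,
) -> ObserverProfile:
    """Draw one synthetic observer of the given age.

    With ``noise_multiplier = 0`` every true threshold equals the task's
    generating-curve value at ``age`` exactly and the latency distribution is
    degenerate at the curve median.
    """
    if not (3.0 <= age <= 23.0):
        raise ValueError(f"age {age} outside [3, 23]")
    if noise_multiplier < 0:
        raise ValueError("noise_multiplier must be >= 0")
    config = config or ObserverConfig()
    rng = _rng_from(seed)
    sigma = config.person_spread * noise_multiplier

    def effect() -> float:
        return math.exp(sigma * rng.standard_normal())

    sqad = evaluate_curve(config.curve("sqAD"), age) * effect()
    if config.couple_smad:
        smad = sqad * (1.0 + (config.smad_factor - 1.0) * effect())
    else:
        smad = config.smad_factor * evaluate_curve(config.curve("sqAD"), age) * effect()
    thresholds = {
        "sqAD": sqad,
        "smAD": smad,
        "TOJ": evaluate_curve(config.curve("TOJ"), age) * effect(),
        "DD": evaluate_curve(config.curve("DD"), age) * effect(),
    }
    for task, theta in thresholds.items():
        if theta <= 0:
            raise ValueError(f"generated {task} threshold is non-positive")

    rt_sigma = config.rt_person_spread * noise_multiplier
    rt_curve = evaluate_curve(config.curve("RT"), age)
    rtvar_curve = evaluate_curve(config.curve("RTVar"), age)
    rt_median = rt_curve * math.exp(rt_sigma * rng.standard_normal())
    # trial-to-trial shape chosen so the within-observer latency scatter is
    # of the order of the variability curve at this age
    shape = noise_multiplier * float(
        np.clip(max(rtvar_curve, 0.0) / rt_curve, 0.0, 0.8)
    )

    comprehension = {
        task: model.probability(age)
        for task, model in config.comprehension.items()
    }
    for task in TASKS:
        comprehension.setdefault(task, 1.0)

    return ObserverProfile(
        observer_id=observer_id,
        age=float(age),
        true_thresholds=thresholds,
        psychometric_slope={t: config.psychometric_slope for t in DISCRIMINATION_TASKS},
        lapse_rate=config.lapse_rate,
        rt_location=0.0,
        rt_scale=rt_median,
        rt_shape=shape,
        comprehension=comprehension,
    )


def perfect_observer(age: float = 20.0, observer_id: int = 0) -> ObserverProfile:
    """An idealized observer: always correct, no lapses, fixed latency."""
    return ObserverProfile(
        observer_id=observer_id,
        age=age,
        true_thresholds={t: 0.0 for t in DISCRIMINATION_TASKS},
        psychometric_slope={t: 4.0 for t in DISCRIMINATION_TASKS},
        lapse_rate=0.0,
        rt_location=0.0,
        rt_scale=200.0,
        rt_shape=0.0,
        comprehension={t: 1.0 for t in TASKS},
    )


def chance_observer(age: float = 20.0, observer_id: int = 0) -> ObserverProfile:
    """A guessing observer: P(correct) = 0.5 at every stimulus difference."""
    return ObserverProfile(
        observer_id=observer_id,
        age=age,
        true_thresholds={t: math.inf for t in DISCRIMINATION_TASKS},
        psychometric_slope={t: 4.0 for t in DISCRIMINATION_TASKS},
        lapse_rate=0.0,
        rt_location=0.0,
        rt_scale=200.0,
        rt_shape=0.0,
        comprehension={t: 1.0 for t in TASKS},
    )


def sample_cohort(
    spec: CohortSpec | None = None,
    config: ObserverConfig | None = None,
    seed: int = 0,
    noise_multiplier: float = 1.0,
) -> list[ObserverProfile]:
    """Sample a cohort of synthetic observers.

    Group sizes are exactly as requested; ages are uniform within each
    recruitment band (or taken from an explicit list).  Each observer's
    randomness comes from a substream keyed by ``(seed, band, index)`` so
    that changing one band's size does not reshuffle the others.
    """
    spec = spec or CohortSpec()
    config = config or ObserverConfig()
    if spec.seed is not None:
        seed = spec.seed
    if spec.noise_multiplier is not None:
        noise_multiplier = spec.noise_multiplier

    observers: list[ObserverProfile] = []
    if isinstance(spec.age_sampling, list):
        for j, age in enumerate(spec.age_sampling):
            rng = np.random.default_rng([seed, 9, j])
            observers.append(
                make_observer(age, config, rng, noise_multiplier, observer_id=j)
            )
        return observers

    next_id = 0
    for band_idx, (label, n) in enumerate(zip(BAND_ORDER, spec.n_per_group)):
        lo, hi = AGE_BANDS[label]
        for j in range(n):
            rng = np.random.default_rng([seed, band_idx, j])
            age = float(rng.uniform(lo, min(hi, 23.0)))
            observers.append(
                make_observer(age, config, rng, noise_multiplier, observer_id=next_id)
            )
            next_id += 1
    return observers


def cohort_to_frame(observers: Sequence[ObserverProfile]) -> pd.DataFrame:
    """Tidy one-row-per-observer table (ages, true parameters)."""
    rows = []
    for obs in observers:
        row = {
            "observer_id": obs.observer_id,
            "age": obs.age,
            "age_band": obs.band,
            "rt_median": obs.rt_median,
            "rt_shape": obs.rt_shape,
            "lapse_rate": obs.lapse_rate,
        }
        for task in DISCRIMINATION_TASKS:
            row[f"true_{task}"] = obs.true_thresholds[task]
        for task in TASKS:
            row[f"comprehension_{task}"] = obs.comprehension.get(task, 1.0)
        rows.append(row)
    return pd.DataFrame(rows)
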