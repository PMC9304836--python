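"""Parametric age-trajectory curves.

Vibrotactile thresholds and latencies decline steeply through early
childhood and level off towards adulthood.  This module defines the small
family of parametric curves used both as *generating* curves for the
synthetic cohort (each task's population-mean trajectory) and as the model
families recovered by :mod:`vibrodev.trajectories`:

``power``
    ``f(x) = a * x**b + c`` — a rapid early decline (``b < 0``) towards an
    adult asymptote ``c``.
``exponential2``
    ``f(x) = a*exp(b*x) + c*exp(d*x)`` — a fast early component plus a slow
    late component.
``linear`` / ``quadratic`` / ``cubic``
    Ordinary polynomials in age, ``a + b*x [+ c*x**2 [+ d*x**3]]``.

``DEFAULT_AGE_CURVES`` holds the package's reference developmental fit for
each of the six battery outcome measures (reaction time, its variability,
and the four discrimination thresholds); ``POLYNOMIAL_AGE_CURVES`` holds the
companion polynomial fits.  Ages are in years, outcomes in ms (timing
measures) or μm (amplitude measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "GeneratingCurve",
    "evaluate_curve",
    "DEFAULT_AGE_CURVES",
    "POLYNOMIAL_AGE_CURVES",
    "MEASURES",
    "DISCRIMINATION_TASKS",
]

#: The six outcome measures of the battery, in canonical order.
MEASURES = ("RT", "RTVar", "sqAD", "smAD", "TOJ", "DD")

#: The four staircase (discrimination) tasks.
DISCRIMINATION_TASKS = ("sqAD", "smAD", "TOJ", "DD")

_FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "power": ("a", "b", "c"),
    "exponential2": ("a", "b", "c", "d"),
    "linear": ("a", "b"),
    "quadratic": ("a", "b", "c"),
    "cubic": ("a", "b", "c", "d"),
}


@dataclass(frozen=True)
class GeneratingCurve:
    """A parametric mean curve of outcome versus age.

    Parameters
    ----------
    family
        One of ``power``, ``exponential2``, ``linear``, ``quadratic``,
        ``cubic``.
    coefficients
        Named coefficients for the family (``a``, ``b``, ... as applicable).
    outcome_units
        ``"ms"`` or ``"um"``; informational only.
    """

    family: str
    coefficients: Mapping[str, float]
    outcome_units: str = "ms"

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown curve family {self.family!r}")
        required = _FAMILY_PARAMS[self.family]
        missing = [k for k in required if k not in self.coefficients]
        if missing:
            raise ValueError(
                f"{self.family} curve missing coefficients {missing}"
            )
        # freeze the mapping so the dataclass is genuinely immutable
        object.__setattr__(
            self,
            "coefficients",
            MappingProxyType({k: float(self.coefficients[k]) for k in required}),
        )

    def __call__(self, age):
        return evaluate_curve(self, age)


def evaluate_curve(curve: GeneratingCurve, age):
    """Evaluate ``curve`` at ``age`` (scalar or array), exact arithmetic.

    No clipping or clamping is applied.  Power curves require ``age > 0``.
    """
    x = np.asarray(age, dtype=float)
    scalar = x.ndim == 0
    c = curve.coefficients
    if curve.family == "power":
        if np.any(x <= 0):
            raise ValueError("power curves are defined only for age > 0")
        out = c["a"] * x ** c["b"] + c["c"]
    elif curve.family == "exponential2":
        out = c["a"] * np.exp(c["b"] * x) + c["c"] * np.exp(c["d"] * x)
    elif curve.family == "linear":
        out = c["a"] + c["b"] * x
    elif curve.family == "quadratic":
        out = c["a"] + c["b"] * x + c["c"] * x**2
    elif curve.family == "cubic":
        out = c["a"] + c["b"] * x + c["c"] * x**2 + c["d"] * x**3
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown curve family {curve.family!r}")
    return float(out) if scalar else out


def _power(a: float, b: float, c: float, units: str) -> GeneratingCurve:
    return GeneratingCurve("power", {"a": a, "b": b, "c": c}, units)


def _exp2(a: float, b: float, c: float, d: float, units: str) -> GeneratingCurve:
    return GeneratingCurve(
        "exponential2", {"a": a, "b": b, "c": c, "d": d}, units
    )


#: Reference nonlinear developmental fit per outcome measure.  These are the
#: package defaults for the synthetic cohort's population-mean trajectories.
DEFAULT_AGE_CURVES: dict[str, GeneratingCurve] = {
    "RT": _power(3158.0, -1.137, 108.2, "ms"),
    "RTVar": _power(1884.0, -1.573, -7.658, "ms"),
    "sqAD": _power(4767.0, -2.591, 53.76, "um"),
    "smAD": _exp2(127.9, -0.031, 1106.0, -0.7311, "um"),
    "TOJ": _power(1004.0, -1.357, 17.8, "ms"),
    "DD": _exp2(726.3, -0.355, 104.6, -0.013, "ms"),
}

#: Companion polynomial developmental fits per outcome measure (the
#: constrained-model counterparts of the nonlinear fits above).
POLYNOMIAL_AGE_CURVES: dict[str, GeneratingCurve] = {
    "RT": GeneratingCurve(
        "cubic", {"a": 1607.534, "b": -262.420, "c": 16.416, "d": -0.335}, "ms"
    ),
    "RTVar": GeneratingCurve(
        "cubic", {"a": 356.093, "b": -70.032, "c": 4.713, "d": -0.102}, "ms"
    ),
    "sqAD": GeneratingCurve(
        "cubic", {"a": 335.310, "b": -56.651, "c": 3.680, "d": -0.077}, "um"
    ),
    "smAD": GeneratingCurve("linear", {"a": 170.984, "b": -5.073}, "um"),
    "TOJ": GeneratingCurve(
        "quadratic", {"a": 176.406, "b": -13.164, "c": 0.311}, "ms"
    ),
    "DD": GeneratingCurve(
        "cubic", {"a": 508.145, "b": -77.298, "c": 4.728, "d": -0.096}, "ms"
    ),
}
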