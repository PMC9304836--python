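"""Nonlinear developmental-trajectory models and model selection.

Task outcomes decline with age towards an adult asymptote.  Three model
families capture this:

* incremental polynomials — start from a line in age, add an ``age**2`` and
  then an ``age**3`` term, keeping each added term only if its coefficient
  is significant (two-sided p < 0.05, uncorrected);
* ``power`` — ``f(x) = a*x**b + c``, fit by trust-region nonlinear least
  squares with a log–log initialization and jittered multistarts;
* ``exponential2`` — ``f(x) = a*exp(b*x) + c*exp(d*x)``, fit by variable
  projection over the two rates (amplitudes solved linearly), initialized by
  exponent peeling (slow component from the oldest ages first), with the
  rates constrained non-positive by default.

Goodness of fit is summarized by SSE, RMSE (``sqrt(SSE / (n - p))``) and
R²; the best family for a task is ranked by RMSE, then R², then SSE, with
ties broken towards fewer coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .config import FitConfig
from .curves import GeneratingCurve, evaluate_curve

__all__ = [
    "ModelFit",
    "SelectionReport",
    "fit_polynomial",
    "fit_polynomial_incremental",
    "fit_power",
    "fit_exponential2",
    "goodness_of_fit",
    "select_best",
    "plateau_age",
]

_POLY_FAMILY = {1: "linear", 2: "quadratic", 3: "cubic"}
_COEF_NAMES = ("a", "b", "c", "d")

#: relative SSE below which a model is treated as numerically perfect and no
#: further polynomial term is attempted (the added coefficient's t-statistic
#: would be 0/0-degenerate)
_PERFECT_FIT_RTOL = 1e-12


@dataclass
class ModelFit:
    """A fitted trajectory model with its goodness-of-fit statistics."""

    family: str
    coefficients: dict[str, float]
    sse: float
    rmse: float
    r_squared: float
    n_obs: int
    n_params: int
    residuals: np.ndarray
    converged: bool = True
    message: str = ""

    def predict(self, age):
        curve = GeneratingCurve(self.family, self.coefficients)
        return evaluate_curve(curve, age)

    def __call__(self, age):
        return self.predict(age)


def _finish_fit(
    family: str,
    coefficients: dict[str, float],
    x: np.ndarray,
    y: np.ndarray,
    converged: bool = True,
    message: str = "",
    rmse_denominator: str = "n_minus_p",
) -> ModelFit:
    curve = GeneratingCurve(family, coefficients)
    residuals = y - evaluate_curve(curve, x)
    stats = _gof(residuals, y, len(coefficients), rmse_denominator)
    return ModelFit(
        family=family,
        coefficients=coefficients,
        sse=stats["sse"],
        rmse=stats["rmse"],
        r_squared=stats["r_squared"],
        n_obs=len(y),
        n_params=len(coefficients),
        residuals=residuals,
        converged=converged,
        message=message,
    )


def _gof(
    residuals: np.ndarray,
    y: np.ndarray,
    n_params: int,
    rmse_denominator: str = "n_minus_p",
) -> dict[str, float]:
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    n = len(y)
    if rmse_denominator == "n_minus_p":
        dof = n - n_params
        if dof <= 0:
            raise ValueError("need n_obs > n_params for the RMSE")
        rmse = math.sqrt(sse / dof)
    else:
        rmse = math.sqrt(sse / n)
    r_squared = math.nan if sst == 0 else 1.0 - sse / sst
    return {"sse": sse, "rmse": rmse, "r_squared": r_squared}


def goodness_of_fit(fit: ModelFit, y: Sequence[float]) -> dict[str, float]:
    """Recompute SSE, RMSE and R² from a fit's residuals.

    Raises if the outcome has zero total variance (R² undefined).
    """
    y = np.asarray(y, dtype=float)
    if float(np.sum((y - y.mean()) ** 2)) == 0.0:
        raise ValueError("R^2 is undefined for an outcome with zero variance")
    return _gof(fit.residuals, y, fit.n_params)


# ---------------------------------------------------------------------------
# polynomial models


def fit_polynomial(
    age: Sequence[float], y: Sequence[float], degree: int
) -> ModelFit:
    """Ordinary least squares fit of a polynomial of fixed degree (1–3)."""
    x = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in _POLY_FAMILY:
        raise ValueError("degree must be 1, 2 or 3")
    design = sm.add_constant(np.column_stack([x**k for k in range(1, degree + 1)]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear ages)")
    model = sm.OLS(y, design).fit()
    coefficients = {
        _COEF_NAMES[k]: float(model.params[k]) for k in range(degree + 1)
    }
    fit = _finish_fit(_POLY_FAMILY[degree], coefficients, x, y)
    fit.message = "ols"
    # stash the p-value of the highest-order term for the incremental rule
    fit._top_term_pvalue = float(model.pvalues[degree])  # type: ignore[attr-defined]
    return fit


def fit_polynomial_incremental(
    age: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    max_degree: int = 3,
) -> ModelFit:
    """Incremental polynomial procedure.

    Fit a line in age; add a quadratic and then a cubic term, retaining each
    added term only if its coefficient's two-sided p-value is below
    ``alpha``.  The procedure stops as soon as a term is rejected, or when
    the current model already fits to machine precision (in which case a
    higher term could only pick up numerical noise).
    """
    x = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 observations")
    if np.any(x <= 0):
        raise ValueError("ages must be positive")

    sst = float(np.sum((y - y.mean()) ** 2))
    current = fit_polynomial(x, y, 1)
    for degree in range(2, max_degree + 1):
        if current.sse <= _PERFECT_FIT_RTOL * max(sst, np.finfo(float).tiny):
            break
        candidate = fit_polynomial(x, y, degree)
        p = candidate._top_term_pvalue  # type: ignore[attr-defined]
        if math.isfinite(p) and p < alpha:
            current = candidate
        else:
            break
    return current


# ---------------------------------------------------------------------------
# power model


def _power_residual(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c = params
    return a * x**b + c - y


def _power_jacobian(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, _ = params
    xb = x**b
    return np.column_stack([xb, a * xb * np.log(x), np.ones_like(x)])


def fit_power(
    age: Sequence[float],
    y: Sequence[float],
    config: FitConfig | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit ``f(x) = a*x**b + c`` by multistart nonlinear least squares.

    Initialization: set ``c0 = min(y)`` and regress ``log(y - c0 + eps)`` on
    ``log(x)`` for ``(a0, b0)``; further starts jitter ``(a, b, c)`` with a
    deterministic generator derived from ``seed``.
    """
    config = config or FitConfig()
    x = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("power fits require positive ages")
    if len(y) < 4:
        raise ValueError("need at least 4 observations")

    spread = float(np.ptp(y))
    eps = 1e-3 * (spread if spread > 0 else max(abs(float(np.mean(y))), 1.0))
    c0 = float(np.min(y))
    logx = np.log(x)
    b0, loga0 = np.polyfit(logx, np.log(y - c0 + eps), 1)
    a0 = float(np.exp(loga0))
    b0 = float(np.clip(b0, -8.0, 8.0))

    rng = np.random.default_rng([seed, 101])
    starts = [np.array([a0, b0, c0])]
    for _ in range(config.n_starts - 1):
        starts.append(
            np.array(
                [
                    a0 * math.exp(0.3 * rng.standard_normal()),
                    float(np.clip(b0 + 0.3 * rng.standard_normal(), -8.0, 8.0)),
                    c0 + 0.1 * (spread if spread > 0 else 1.0) * rng.standard_normal(),
                ]
            )
        )

    best = None
    lower = np.array([-np.inf, -10.0, -np.inf])
    upper = np.array([np.inf, 10.0, np.inf])
    for x0 in starts:
        try:
            sol = least_squares(
                _power_residual,
                np.clip(x0, lower + 1e-9, upper - 1e-9),
                jac=_power_jacobian,
                bounds=(lower, upper),
                args=(x, y),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=10_000,
            )
        except Exception:  # pragma: no cover - pathological start
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        fit = _finish_fit(
            "power",
            {"a": a0, "b": b0, "c": c0},
            x,
            y,
            converged=False,
            message="no start converged",
            rmse_denominator=config.rmse_denominator,
        )
        return fit
    a, b, c = best.x
    return _finish_fit(
        "power",
        {"a": float(a), "b": float(b), "c": float(c)},
        x,
        y,
        converged=True,
        message=best.message,
        rmse_denominator=config.rmse_denominator,
    )


# ---------------------------------------------------------------------------
# two-term exponential model (variable projection over the two rates)


def _exp2_amplitudes(rates: np.ndarray, x: np.ndarray, y: np.ndarray):
    basis = np.exp(np.outer(x, rates))
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return coef, basis


def _exp2_residual(rates: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, basis = _exp2_amplitudes(rates, x, y)
    return basis @ coef - y


def _peel_rates(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exponent-peeling initialization: slow rate from the oldest ages."""
    eps = 1e-9 + 1e-6 * float(np.max(np.abs(y)))
    old = x >= np.quantile(x, 2.0 / 3.0)
    d0 = -0.05
    c0 = max(float(np.mean(y[old])), eps)
    if old.sum() >= 2:
        slope, intercept = np.polyfit(x[old], np.log(np.clip(y[old], eps, None)), 1)
        if math.isfinite(slope):
            d0 = float(np.clip(slope, -5.0, -1e-4))
            c0 = float(np.exp(intercept))
    resid = y - c0 * np.exp(d0 * x)
    young = x <= np.quantile(x, 1.0 / 3.0)
    usable = young & (resid > eps)
    b0 = 10.0 * d0
    if usable.sum() >= 2:
        slope, _ = np.polyfit(x[usable], np.log(resid[usable]), 1)
        if math.isfinite(slope) and slope < d0:
            b0 = float(np.clip(slope, -10.0, d0))
    return float(np.clip(b0, -10.0, -1e-3)), d0


def fit_exponential2(
    age: Sequence[float],
    y: Sequence[float],
    config: FitConfig | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit ``f(x) = a*exp(b*x) + c*exp(d*x)`` (rates <= 0 by default).

    The two rates are optimized by trust-region least squares with the
    amplitudes solved linearly at every step (variable projection), which
    makes the 4-parameter problem far better conditioned.  Starts: exponent
    peeling, a small canonical grid of (fast, slow) rate pairs, and jittered
    copies.  The returned coefficients order the fast component first
    (``b <= d``).
    """
    config = config or FitConfig()
    x = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 observations")

    hi = 0.0 if config.decreasing_rates else 10.0
    lo = -10.0
    starts = [np.array(_peel_rates(x, y))]
    for pair in ((-0.5, -0.02), (-1.0, -0.05), (-2.0, -0.1), (-0.2, -0.01)):
        starts.append(np.array(pair))
    rng = np.random.default_rng([seed, 202])
    base = starts[0]
    for _ in range(max(config.n_starts - len(starts), 0)):
        starts.append(base * np.exp(0.4 * rng.standard_normal(2)))

    best = None
    for x0 in starts:
        x0 = np.clip(np.sort(x0), lo + 1e-6, hi - 1e-6)
        if x0[1] - x0[0] < 1e-6:
            x0[0] -= 1e-3
        try:
            sol = least_squares(
                _exp2_residual,
                x0,
                bounds=([lo, lo], [hi, hi]),
                args=(x, y),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=10_000,
            )
        except Exception:  # pragma: no cover
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        b0, d0 = starts[0]
        coef, _ = _exp2_amplitudes(np.array([b0, d0]), x, y)
        return _finish_fit(
            "exponential2",
            {"a": float(coef[0]), "b": float(b0), "c": float(coef[1]), "d": float(d0)},
            x,
            y,
            converged=False,
            message="no start converged",
            rmse_denominator=config.rmse_denominator,
        )

    rates = best.x
    coef, _ = _exp2_amplitudes(rates, x, y)
    order = np.argsort(rates)  # fast (most negative) rate first
    b, d = (float(rates[i]) for i in order)
    a, c = (float(coef[i]) for i in order)
    return _finish_fit(
        "exponential2",
        {"a": a, "b": b, "c": c, "d": d},
        x,
        y,
        converged=True,
        message=best.message,
        rmse_denominator=config.rmse_denominator,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionReport:
    """Ranked candidate fits for one task."""

    table: pd.DataFrame  # family, n_params, sse, rmse, r_squared, converged
    chosen: str
    fits: Mapping[str, ModelFit]

    @property
    def best(self) -> ModelFit:
        return self.fits[self.chosen]


def select_best(candidates: Mapping[str, ModelFit]) -> SelectionReport:
    """Rank candidate fits by RMSE, then R², then SSE; parsimony tie-break.

    Non-converged candidates are recorded but excluded from the ranking;
    with no converged candidate a ``ValueError`` is raised.
    """
    rows = []
    for name, fit in candidates.items():
        rows.append(
            {
                "family": name,
                "n_params": fit.n_params,
                "sse": fit.sse,
                "rmse": fit.rmse,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    eligible = [(name, fit) for name, fit in candidates.items() if fit.converged]
    if not eligible:
        raise ValueError("no converged candidate to select from")
    chosen = min(
        eligible,
        key=lambda item: (
            item[1].rmse,
            -(item[1].r_squared if math.isfinite(item[1].r_squared) else -math.inf),
            item[1].sse,
            item[1].n_params,
        ),
    )[0]
    table = table.sort_values(["rmse", "n_params"]).reset_index(drop=True)
    return SelectionReport(table=table, chosen=chosen, fits=dict(candidates))


def plateau_age(
    fit,
    epsilon_fraction: float = 0.05,
    age_range: tuple[float, float] = (3.0, 23.0),
    tol: float = 1e-3,
) -> float:
    """Smallest age at which the fitted curve is within ``epsilon_fraction``
    of its value at the upper age limit.

    ``fit`` is anything callable on an age array (a :class:`ModelFit` or a
    generating curve).  The curve must be monotone non-increasing over the
    range; otherwise the plateau is undefined and a ``ValueError`` is
    raised.  Resolved by bisection to ``tol`` years.
    """
    lo, hi = age_range
    grid = np.linspace(lo, hi, 801)
    values = np.asarray(fit(grid), dtype=float)
    scale = max(float(np.max(np.abs(values))), 1e-12)
    if np.any(np.diff(values) > 1e-9 * scale):
        raise ValueError("plateau age is undefined for a non-monotone fit")

    target = float(values[-1])
    cutoff = target + epsilon_fraction * abs(target)

    def above(age: float) -> bool:
        return float(fit(np.asarray(age, dtype=float))) > cutoff

    if not above(lo):
        return lo
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if above(mid):
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
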