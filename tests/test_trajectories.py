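"""Trajectory fitting: polynomial/power/exponential recovery and selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vibrodev.curves import DEFAULT_AGE_CURVES, POLYNOMIAL_AGE_CURVES
from vibrodev.trajectories import (
    ModelFit,
    fit_exponential2,
    fit_polynomial,
    fit_polynomial_incremental,
    fit_power,
    goodness_of_fit,
    plateau_age,
    select_best,
)

AGES = np.arange(3.0, 23.0001, 0.25)


class TestIncrementalPolynomial:
    def test_linear_data_stops_at_linear(self):
        ages = np.arange(3.0, 24.0)
        y = POLYNOMIAL_AGE_CURVES["smAD"](ages)
        fit = fit_polynomial_incremental(ages, y)
        assert fit.family == "linear"
        assert fit.coefficients["a"] == pytest.approx(170.984, rel=1e-9)
        assert fit.coefficients["b"] == pytest.approx(-5.073, rel=1e-9)

    def test_quadratic_data_keeps_quadratic_rejects_cubic(self):
        ages = np.arange(3.0, 23.0001, 0.5)
        y = POLYNOMIAL_AGE_CURVES["TOJ"](ages)
        fit = fit_polynomial_incremental(ages, y)
        assert fit.family == "quadratic"
        assert fit.coefficients["c"] == pytest.approx(0.311, rel=1e-6)

    def test_cubic_data_recovers_cubic(self):
        ages = np.arange(3.0, 23.0001, 0.5)
        y = POLYNOMIAL_AGE_CURVES["RT"](ages)
        fit = fit_polynomial_incremental(ages, y)
        assert fit.family == "cubic"
        for name, expected in zip("abcd", (1607.534, -262.420, 16.416, -0.335)):
            assert fit.coefficients[name] == pytest.approx(expected, rel=1e-6)

    def test_constant_outcome_gives_flat_line(self):
        ages = np.arange(3.0, 24.0)
        fit = fit_polynomial_incremental(ages, np.full_like(ages, 42.0))
        assert fit.family == "linear"
        assert fit.coefficients["b"] == pytest.approx(0.0, abs=1e-10)

    def test_noisy_quadratic_term_rejected_when_absent(self):
        rng = np.random.default_rng(5)
        ages = np.arange(3.0, 24.0)
        y = 100.0 - 2.0 * ages + rng.normal(0, 3.0, ages.size)
        fit = fit_polynomial_incremental(ages, y)
        assert fit.family == "linear"

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_polynomial([5.0] * 10, list(range(10)), 2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_nesting_sse_monotone(self, seed):
        """OLS projection: richer polynomials never fit worse."""
        rng = np.random.default_rng(seed)
        ages = np.linspace(3, 23, 30)
        y = rng.normal(100, 20, ages.size)
        sses = [fit_polynomial(ages, y, d).sse for d in (1, 2, 3)]
        assert sses[0] >= sses[1] - 1e-8 >= sses[2] - 2e-8


class TestFitPower:
    def test_noiseless_recovery_of_default_curves(self):
        for task in ("RT", "RTVar", "sqAD", "TOJ"):
            curve = DEFAULT_AGE_CURVES[task]
            fit = fit_power(AGES, curve(AGES))
            assert fit.converged
            for name in ("a", "b", "c"):
                assert fit.coefficients[name] == pytest.approx(
                    curve.coefficients[name], rel=1e-4, abs=1e-6
                ), task

    def test_self_generated_oracle(self):
        y = 2.0 * AGES ** (-1.0) + 5.0
        fit = fit_power(AGES, y)
        assert fit.coefficients["a"] == pytest.approx(2.0, rel=1e-4)
        assert fit.coefficients["b"] == pytest.approx(-1.0, rel=1e-4)
        assert fit.coefficients["c"] == pytest.approx(5.0, rel=1e-4)

    def test_constant_outcome_fits_a_plateau(self):
        fit = fit_power(AGES, np.full_like(AGES, 7.0))
        assert fit.predict(AGES) == pytest.approx(np.full_like(AGES, 7.0), abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            fit_power([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])


class TestFitExponential2:
    def test_noiseless_recovery_of_default_curves(self):
        for task in ("smAD", "DD"):
            curve = DEFAULT_AGE_CURVES[task]
            fit = fit_exponential2(AGES, curve(AGES))
            assert fit.converged
            # fast component first
            assert fit.coefficients["b"] <= fit.coefficients["d"]
            rates = sorted((curve.coefficients["b"], curve.coefficients["d"]))
            assert fit.coefficients["b"] == pytest.approx(rates[0], rel=1e-3)
            assert fit.coefficients["d"] == pytest.approx(rates[1], rel=1e-3)

    def test_self_generated_oracle_curve_level(self):
        y = 100.0 * np.exp(-0.5 * AGES) + 50.0 * np.exp(-0.01 * AGES)
        fit = fit_exponential2(AGES, y)
        assert fit.predict(AGES) == pytest.approx(y, rel=1e-3)

    def test_single_exponential_is_nested(self):
        y = 80.0 * np.exp(-0.4 * AGES)
        fit = fit_exponential2(AGES, y)
        assert fit.predict(AGES) == pytest.approx(y, rel=1e-3, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-6)


class TestGoodnessOfFit:
    def test_hand_computed_residuals(self):
        fit = ModelFit(
            family="linear",
            coefficients={"a": 0.0, "b": 0.0},
            sse=0.0, rmse=0.0, r_squared=0.0,
            n_obs=5, n_params=2,
            residuals=np.array([1.0, -1.0, 1.0, -1.0, 0.0]),
        )
        stats = goodness_of_fit(fit, [10.0, 12.0, 11.0, 13.0, 9.0])
        assert stats["sse"] == pytest.approx(4.0)
        assert stats["rmse"] == pytest.approx(math.sqrt(4.0 / 3.0))

    def test_perfect_fit(self):
        fit = ModelFit("linear", {"a": 0, "b": 1}, 0, 0, 1, 5, 2, np.zeros(5))
        stats = goodness_of_fit(fit, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert stats == {"sse": 0.0, "rmse": 0.0, "r_squared": 1.0}

    def test_mean_only_model_has_zero_r_squared(self):
        y = np.array([4.0, 6.0, 5.0, 7.0, 3.0])
        fit = ModelFit("linear", {"a": 5, "b": 0}, 0, 0, 0, 5, 1, y - y.mean())
        assert goodness_of_fit(fit, y)["r_squared"] == pytest.approx(0.0)

    def test_zero_variance_outcome_signalled(self):
        fit = ModelFit("linear", {"a": 5, "b": 0}, 0, 0, 0, 5, 1, np.zeros(5))
        with pytest.raises(ValueError):
            goodness_of_fit(fit, [5.0] * 5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_r_squared_consistency(self, seed):
        rng = np.random.default_rng(seed)
        ages = np.linspace(3, 23, 40)
        y = DEFAULT_AGE_CURVES["TOJ"](ages) + rng.normal(0, 10, 40)
        fit = fit_polynomial(ages, y, 2)
        sst = float(np.sum((y - y.mean()) ** 2))
        assert fit.r_squared == pytest.approx(1 - fit.sse / sst, rel=1e-12)


class TestSelectBest:
    def _fit(self, family, rmse, r2, sse, n_params, converged=True):
        return ModelFit(family, {}, sse, rmse, r2, 50, n_params,
                        np.zeros(1), converged=converged)

    def test_lowest_rmse_wins(self):
        report = select_best({
            "power": self._fit("power", 124.6, 0.67, 2.0e6, 3),
            "exponential2": self._fit("exponential2", 130.0, 0.66, 2.2e6, 4),
        })
        assert report.chosen == "power"

    def test_parsimony_tie_break(self):
        report = select_best({
            "exponential2": self._fit("exponential2", 50.0, 0.5, 1e5, 4),
            "power": self._fit("power", 50.0, 0.5, 1e5, 3),
        })
        assert report.chosen == "power"

    def test_non_converged_excluded(self):
        report = select_best({
            "power": self._fit("power", 1.0, 0.99, 10.0, 3, converged=False),
            "exponential2": self._fit("exponential2", 60.0, 0.5, 1e5, 4),
        })
        assert report.chosen == "exponential2"
        with pytest.raises(ValueError):
            select_best({"power": self._fit("power", 1.0, 0.9, 1.0, 3, converged=False)})


class TestPlateauAge:
    def test_constant_curve_plateaus_at_left_edge(self):
        fit = ModelFit("linear", {"a": 10.0, "b": 0.0}, 0, 0, 0, 5, 2, np.zeros(5))
        assert plateau_age(fit) == pytest.approx(3.0)

    def test_dd_curve_matches_bisection_oracle(self):
        curve = DEFAULT_AGE_CURVES["DD"]
        age = plateau_age(curve, epsilon_fraction=0.05)
        # independent oracle: dense-grid scan for the 5% band around f(23)
        grid = np.linspace(3.0, 23.0, 200_001)
        values = curve(grid)
        cutoff = values[-1] * 1.05
        oracle = grid[np.argmax(values <= cutoff)]
        assert 3.0 < age < 23.0
        assert age == pytest.approx(oracle, abs=0.01)

    def test_steeper_decay_never_plateaus_later(self):
        ref = DEFAULT_AGE_CURVES["DD"]
        ages = [
            plateau_age(
                type(ref)("exponential2",
                          {**ref.coefficients, "b": rate},
                          ref.outcome_units)
            )
            for rate in (-0.2, -0.355, -0.8, -2.0)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(ages, ages[1:]))

    def test_non_monotone_fit_rejected(self):
        fit = ModelFit("quadratic", {"a": 0.0, "b": -10.0, "c": 0.5},
                       0, 0, 0, 5, 3, np.zeros(5))
        with pytest.raises(ValueError):
            plateau_age(fit)
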