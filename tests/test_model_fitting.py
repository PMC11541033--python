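from fractions import Fraction

import numpy as np
import pytest
import statsmodels.api as sm

from pigbel.model_fitting import (
    BrokenLineFit,
    ModelFit,
    compare_models,
    fit_aa_equations,
    fit_broken_line,
    fit_exponential,
    fit_linear,
    ranking_frame,
)

from conftest import make_dataset


def dense_grid_sse(y: np.ndarray, x: np.ndarray, n_grid: int = 4000) -> float:
    """Brute-force broken-line SSE: minimize over a dense breakpoint grid,
    solving the conditional OLS at every grid point."""
    best = np.inf
    for R in np.linspace(x.min(), x.max(), n_grid):
        h = np.maximum(R - x, 0.0)
        X = np.column_stack([np.ones_like(x), h])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        best = min(best, float(r @ r))
    return best


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_linear(3 + 2 * x, {"x": x})
        assert fit.coefficients["C1"] == pytest.approx(3.0, abs=1e-10)
        assert fit.coefficients["C2"] == pytest.approx(2.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_exact_rational_normal_equations(self):
        # n = 6 integer dataset solved with exact Fraction arithmetic
        x = [1, 2, 3, 5, 8, 13]
        y = [4, 7, 8, 13, 21, 30]
        n = len(x)
        sx = Fraction(sum(x))
        sy = Fraction(sum(y))
        sxx = Fraction(sum(v * v for v in x))
        sxy = Fraction(sum(a * b for a, b in zip(x, y)))
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        fit = fit_linear(np.array(y, float), {"x": np.array(x, float)})
        assert fit.coefficients["C1"] == pytest.approx(float(intercept), abs=1e-10)
        assert fit.coefficients["C2"] == pytest.approx(float(slope), abs=1e-10)
        # rmse from the exact residuals
        resid = [Fraction(yi) - (intercept + slope * xi) for xi, yi in zip(x, y)]
        sse = sum(r * r for r in resid)
        assert fit.rmse == pytest.approx(float(sse / (n - 2)) ** 0.5, rel=1e-10)

    def test_two_predictors_match_lstsq(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        y = 1.5 - 0.4 * x1 + 0.9 * x2 + rng.normal(0, 0.2, 30)
        fit = fit_linear(y, {"a": x1, "b": x2})
        X = np.column_stack([np.ones(30), x1, x2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.coefficients["C1"] == pytest.approx(beta[0], rel=1e-10)
        assert fit.coefficients["C2"] == pytest.approx(beta[1], rel=1e-10)
        assert fit.coefficients["C3"] == pytest.approx(beta[2], rel=1e-10)

    def test_collinear_predictors_error(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(2 * x, {"a": x, "b": 3 * x})

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(10, 110, 50)
        y = 20 - 0.08 * x + rng.normal(0, 2, 50)
        fit = fit_linear(y, {"x": x})
        resid = y - fit.predict(x)
        assert abs(resid.sum()) < 1e-8

    def test_r2_monotone_in_nested_models(self):
        rng = np.random.default_rng(9)
        x1 = rng.uniform(10, 110, 60)
        x2 = rng.uniform(1, 3, 60)
        y = 20 - 0.08 * x1 - 0.5 * x2 + rng.normal(0, 2, 60)
        r2_one = fit_linear(y, {"x1": x1}).r2
        r2_two = fit_linear(y, {"x1": x1, "x2": x2}).r2
        assert r2_two >= r2_one


class TestFitExponential:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 100, 40)
        fit = fit_exponential(5 * np.exp(-0.01 * x), {"x": x})
        assert fit.coefficients["C1"] == pytest.approx(5.0, rel=1e-8)
        assert fit.coefficients["C2"] == pytest.approx(-0.01, rel=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_refinement_never_worsens_the_initializer(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(10, 110, 40)
        y = 20.8 * np.exp(-0.00475 * x) + rng.normal(0, 2.0, 40)
        y = np.maximum(y, 0.5)
        fit = fit_exponential(y, {"x": x})
        init = sm.OLS(np.log(y), sm.add_constant(x)).fit().params
        mu0 = np.exp(init[0]) * np.exp(init[1] * x)
        init_sse = float((y - mu0) @ (y - mu0))
        assert fit.sse <= init_sse + 1e-9

    def test_two_predictor_noiseless(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.uniform(0, 5, 30), rng.uniform(0, 5, 30)
        y = 2.0 * np.exp(0.3 * x1 - 0.2 * x2)
        fit = fit_exponential(y, {"a": x1, "b": x2})
        assert fit.coefficients["C1"] == pytest.approx(2.0, rel=1e-7)
        assert fit.coefficients["C2"] == pytest.approx(0.3, rel=1e-7)
        assert fit.coefficients["C3"] == pytest.approx(-0.2, rel=1e-7)

    def test_requires_enough_positive_responses(self):
        x = np.arange(8.0)
        y = -np.ones(8)
        with pytest.raises(ValueError, match="positive"):
            fit_exponential(y, {"x": x})


class TestFitBrokenLine:
    def test_noiseless_exact_recovery(self):
        x = np.arange(10.0, 120.0, 10.0)
        y = 14.78 + 0.102 * np.maximum(62.0 - x, 0.0)
        fit = fit_broken_line(y, x)
        assert fit.breakpoint == pytest.approx(62.0, abs=1e-4)
        assert fit.plateau == pytest.approx(14.78, abs=1e-6)
        assert fit.slope == pytest.approx(0.102, abs=1e-6)
        assert fit.rmse == pytest.approx(0.0, abs=1e-6)
        assert not fit.degenerate

    def test_constant_response_is_flat_degenerate_fit(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        fit = fit_broken_line(np.full(5, 7.0), x)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.degenerate

    @pytest.mark.parametrize("seed", range(10))
    def test_profiled_search_beats_dense_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 40))
        x = rng.uniform(10, 110, n)
        y = 14.78 + 0.102 * np.maximum(62.0 - x, 0.0) + rng.normal(0, 2.0, n)
        fit = fit_broken_line(y, x)
        assert fit.sse <= dense_grid_sse(y, x) + 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_sse_never_above_plain_linear(self, seed):
        # the straight line is the boundary member of the broken-line family
        rng = np.random.default_rng(100 + seed)
        x = rng.uniform(10, 110, 30)
        y = 18 - 0.05 * x + rng.normal(0, 1.5, 30)
        bl = fit_broken_line(y, x)
        lin = fit_linear(y, {"x": x})
        assert bl.sse <= lin.sse + 1e-8

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(10, 110, 60)
        y = 14.78 + 0.102 * np.maximum(62.0 - x, 0.0) + rng.normal(0, 2.0, 60)
        fit = fit_broken_line(y, x)
        assert abs((y - fit.predict(x)).sum()) < 1e-7

    def test_increasing_orientation_mirrors(self):
        x = np.arange(10.0, 120.0, 10.0)
        y = 5.0 + 0.2 * np.maximum(x - 62.0, 0.0)
        fit = fit_broken_line(y, x, orientation="increasing")
        assert fit.breakpoint == pytest.approx(62.0, abs=1e-3)
        assert fit.plateau == pytest.approx(5.0, abs=1e-5)
        assert fit.slope == pytest.approx(0.2, abs=1e-5)

    def test_breakpoint_within_data_range(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(10, 110, 25)
        y = rng.normal(15, 3, 25)
        fit = fit_broken_line(y, x)
        assert x.min() <= fit.breakpoint <= x.max()

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError):
            fit_broken_line(np.arange(5.0), np.array([1.0, 1.0, 2.0, 2.0, 2.0]))


class TestAAEquations:
    def test_noiseless_exact_recovery(self):
        cp = np.linspace(6, 29, 20)
        ds = make_dataset(ibw=np.full(20, 50.0), bel_cp=cp,
                          lys=0.148 + 0.017 * cp)
        (eq,) = fit_aa_equations(ds)
        assert eq.aa == "Lys"
        assert eq.intercept == pytest.approx(0.148, abs=1e-10)
        assert eq.slope == pytest.approx(0.017, abs=1e-12)
        assert eq.r2 == pytest.approx(1.0)

    def test_missing_aa_skipped_not_errored(self):
        cp = np.linspace(6, 29, 10)
        ds = make_dataset(ibw=np.full(10, 50.0), bel_cp=cp,
                          lys=0.148 + 0.017 * cp,
                          trp=[None] * 10)
        eqs = fit_aa_equations(ds)
        assert [e.aa for e in eqs] == ["Lys"]

    def test_insufficient_pairs_skipped(self):
        ds = make_dataset(ibw=[50, 50, 50], bel_cp=[10.0, 15.0, 20.0],
                          lys=[0.3, 0.4, None])
        assert fit_aa_equations(ds) == []


class TestCompareModels:
    @staticmethod
    def _fit(family, rmse, r2, ncoef=2):
        return ModelFit(family=family,
                        coefficients={f"C{i + 1}": 0.0 for i in range(ncoef)},
                        se={}, predictor_names=("x",)[:1], rmse=rmse, r2=r2,
                        p_model=0.001, n=117)

    def test_lower_rmse_wins(self):
        lin = self._fit("linear", 4.87, 0.11)
        expo = self._fit("exponential", 4.86, 0.12)
        assert compare_models([lin, expo])[0] is expo

    def test_tie_broken_by_parsimony(self):
        a = self._fit("linear", 4.9, 0.1, ncoef=3)
        b = self._fit("linear", 4.9, 0.1, ncoef=2)
        assert compare_models([a, b])[0] is b

    def test_single_fit_returned(self):
        f = self._fit("linear", 1.0, 0.5)
        assert compare_models([f]) == [f]

    def test_ranking_frame_is_ordered(self):
        fits = [self._fit("linear", 4.87, 0.11),
                self._fit("exponential", 4.86, 0.12)]
        frame = ranking_frame(fits)
        assert list(frame["rank"]) == [1, 2]
        assert frame.iloc[0]["family"] == "exponential"
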