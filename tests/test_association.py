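"""Regression screens and recursive path analysis."""

import numpy as np
import pandas as pd
import pytest

import desertmf as d
from desertmf.association import PathEdge, PathFit, direct_effect


def chain_data(n, a=0.6, b=0.5, seed=0):
    """x → m → y with standardized coefficients a and b."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1 - a**2) * rng.standard_normal(n)
    y = b * m + np.sqrt(1 - b**2) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


class TestOlsScreen:
    def test_exact_linear(self):
        x = np.arange(10.0)
        fit = d.ols_screen(2 * x, x, form="linear")
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_single_peak_quadratic(self):
        x = np.linspace(-3, 3, 15)
        fit = d.ols_screen(-(x**2), x, form="quadratic")
        assert fit.coefficients["x2"] == pytest.approx(-1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.uniform(-2, 2, 40)
        y = rng.standard_normal(40)
        fit = d.ols_screen(y, x, form="quadratic")
        X = np.column_stack([np.ones_like(x), x, x**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.coefficients["x2"] == pytest.approx(beta[2], abs=1e-10)

    def test_quadratic_never_below_linear(self, rng):
        x = rng.uniform(0, 5, 50)
        y = 0.3 * x + rng.standard_normal(50)
        lin = d.ols_screen(y, x, form="linear")
        quad = d.ols_screen(y, x, form="quadratic")
        assert quad.r2 >= lin.r2 - 1e-12

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            d.ols_screen(np.arange(10.0), np.ones(10), form="linear")


class TestPathModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            d.PathModel(edges=(("a", "b"), ("b", "c"), ("c", "a")))

    def test_from_strings(self):
        model = d.PathModel.from_strings(["pH -> MF", "CN -> MF  # soil chemistry", ""])
        assert model.edges == (("pH", "MF"), ("CN", "MF"))
        assert model.exogenous == ("pH", "CN")
        assert model.endogenous == ("MF",)


class TestFitPathModel:
    def test_chain_parameter_recovery(self):
        data = chain_data(5000, seed=12)
        fit = d.fit_path_model(d.PathModel(edges=(("x", "m"), ("m", "y"))), data)
        assert fit.coefficient("x", "m") == pytest.approx(0.6, abs=0.05)
        assert fit.coefficient("m", "y") == pytest.approx(0.5, abs=0.05)
        assert d.indirect_effect(fit, "x", "y") == pytest.approx(0.30, abs=0.05)
        assert fit.df == 1 and fit.nc >= 0 and 0 <= fit.cfi <= 1

    def test_saturated_model_perfect_fit(self):
        data = chain_data(300, seed=3)
        model = d.PathModel(edges=(("x", "m"), ("x", "y"), ("m", "y")))
        fit = d.fit_path_model(model, data)
        assert fit.df == 0
        assert fit.chi2 == 0.0
        assert fit.cfi == 1.0
        # saturated: implied equals the sample correlation matrix
        S = np.corrcoef(data.to_numpy(), rowvar=False)
        np.testing.assert_allclose(fit.implied.values, S, atol=1e-8)

    def test_null_edge_coefficient_near_zero(self):
        rng = np.random.default_rng(8)
        n = 2000
        data = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        fit = d.fit_path_model(d.PathModel(edges=(("a", "b"),)), data)
        assert abs(fit.coefficient("a", "b")) < 3 / np.sqrt(n)

    def test_path_pvalues_from_t(self):
        data = chain_data(400, seed=5)
        fit = d.fit_path_model(d.PathModel(edges=(("x", "m"), ("m", "y"))), data)
        strong = next(e for e in fit.edges if e.source == "x")
        assert strong.p_value < 1e-6

    def test_wright_total_effect_matches_marginal_slope(self):
        # fully recursive model with a single exogenous variable
        data = chain_data(3000, seed=21)
        model = d.PathModel(edges=(("x", "m"), ("x", "y"), ("m", "y")))
        fit = d.fit_path_model(model, data)
        z = (data - data.mean()) / data.std(ddof=1)
        marginal = np.polyfit(z["x"], z["y"], 1)[0]
        assert d.total_effect(fit, "x", "y") == pytest.approx(marginal, abs=1e-6)

    def test_chi2_calibration_under_true_model(self):
        # chain model has df = 1; under the generating model the mean chi-square
        # should sit near its df (large per-dataset n keeps the LR statistic in
        # its asymptotic regime)
        chis = []
        model = d.PathModel(edges=(("x", "m"), ("m", "y")))
        for rep in range(400):
            data = chain_data(2000, seed=1000 + rep)
            chis.append(d.fit_path_model(model, data).chi2)
        mean = float(np.mean(chis))
        assert mean == pytest.approx(1.0, rel=0.15)

    def test_large_sample_bias_small(self):
        data = chain_data(10000, seed=77)
        fit = d.fit_path_model(d.PathModel(edges=(("x", "m"), ("m", "y"))), data)
        assert abs(fit.coefficient("x", "m") - 0.6) < 0.02
        assert abs(fit.coefficient("m", "y") - 0.5) < 0.02

    def test_heywood_flagging(self):
        # suppressor setup: two near-collinear predictors with opposite-signed
        # effects drive standardized partial coefficients past |1|
        rng = np.random.default_rng(4)
        n = 500
        x1 = rng.standard_normal(n)
        x2 = 0.95 * x1 + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        y = 2.0 * x1 - 1.5 * x2 + 0.2 * rng.standard_normal(n)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        fit = d.fit_path_model(d.PathModel(edges=(("x1", "y"), ("x2", "y"))), data)
        assert any(abs(e.coefficient) > 1 for e in fit.edges)
        assert len(fit.heywood) >= 1


class TestIndirectEffect:
    def _fit_with(self, edges_coefs):
        edges = tuple(PathEdge(a, b, c, 0.0, 1.0) for a, b, c in edges_coefs)
        model = d.PathModel(edges=tuple((a, b) for a, b, _ in edges_coefs))
        implied = pd.DataFrame(np.eye(len(model.variables)),
                               index=model.variables, columns=model.variables)
        return PathFit(model=model, edges=edges, residual_variances={},
                       implied=implied, chi2=0.0, df=0, nc=0.0, cfi=1.0, n=100)

    def test_single_chain_product(self):
        fit = self._fit_with([("x", "m", 0.5), ("m", "y", 0.4)])
        assert d.indirect_effect(fit, "x", "y") == pytest.approx(0.20)

    def test_no_path_is_zero(self):
        fit = self._fit_with([("x", "m", 0.5), ("y", "m", 0.4)])
        assert d.indirect_effect(fit, "x", "y") == 0.0

    def test_parallel_paths_sum(self):
        fit = self._fit_with([
            ("x", "m1", 0.5), ("m1", "y", 0.2),   # product 0.10
            ("x", "m2", 0.4), ("m2", "y", -0.1),  # product -0.04
        ])
        assert d.indirect_effect(fit, "x", "y") == pytest.approx(0.06)

    def test_direct_effect_zero_when_absent(self):
        fit = self._fit_with([("x", "m", 0.5), ("m", "y", 0.4)])
        assert direct_effect(fit, "x", "y") == 0.0
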