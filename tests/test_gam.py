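"""Penalized-spline GAM engine: bases, penalties, fitting, selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

import whistlegam as wg
from whistlegam import gam
from whistlegam.errors import ValidationError
from whistlegam.gam import _crs_design, _crs_matrices, _pirls


class TestBases:
    def test_cyclic_rows_periodic(self):
        knots = np.linspace(0, 24, 8, endpoint=False)
        F, _ = _crs_matrices(knots, cyclic=True, period=24.0)
        a = _crs_design(np.array([0.0, 3.7, 12.0]), knots, F, True, 24.0)
        b = _crs_design(np.array([24.0, 27.7, 36.0]), knots, F, True, 24.0)
        assert np.allclose(a, b, atol=1e-10)

    def test_natural_basis_interpolates_knot_values(self):
        kn = np.sort(np.random.default_rng(0).uniform(0, 10, 9))
        F, _ = _crs_matrices(kn, cyclic=False, period=None)
        assert np.allclose(_crs_design(kn, kn, F, False, None), np.eye(9), atol=1e-10)

    def test_linear_function_has_zero_curvature_penalty(self):
        kn = np.linspace(0, 10, 7)
        _, S = _crs_matrices(kn, cyclic=False, period=None)
        beta = 2.0 + 3.0 * kn  # a straight line through the knot values
        assert beta @ S @ beta == pytest.approx(0.0, abs=1e-10)

    def test_penalty_equals_integrated_squared_second_derivative(self):
        """Quadratic form equals ∫(g″)² of the natural-spline interpolant."""
        rng = np.random.default_rng(1)
        kn = np.sort(rng.uniform(0, 10, 8))
        _, S = _crs_matrices(kn, cyclic=False, period=None)
        beta = rng.normal(size=8)
        g = CubicSpline(kn, beta, bc_type="natural")
        xs = np.linspace(kn[0], kn[-1], 40001)
        integral = np.trapezoid(g(xs, 2) ** 2, xs)
        assert beta @ S @ beta == pytest.approx(integral, rel=1e-6)

    def test_cyclic_penalty_matches_numeric_integral(self):
        knots = np.linspace(0, 1, 9, endpoint=False)
        F, S = _crs_matrices(knots, cyclic=True, period=1.0)
        rng = np.random.default_rng(2)
        beta = rng.normal(size=9)
        xs = np.linspace(0, 1, 20001)
        X = _crs_design(xs, knots, F, True, 1.0)
        vals = X @ beta
        second = np.gradient(np.gradient(vals, xs), xs)
        integral = np.trapezoid(second[10:-10] ** 2, xs[10:-10])
        assert beta @ S @ beta == pytest.approx(integral, rel=1e-2)

    def test_k_larger_than_distinct_values_rejected(self):
        data = pd.DataFrame({"x": np.repeat([1.0, 2.0, 3.0], 10)})
        with pytest.raises(ValidationError):
            wg.build_basis(gam.BasisSpec("thinplate", ("x",), k=10), data)

    def test_tensor_block_shape_and_penalty_count(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"a": rng.uniform(size=80), "b": rng.uniform(size=80)})
        X, pens = wg.build_basis(gam.BasisSpec("tensor", ("a", "b"), k=4), data)
        assert X.shape == (80, 15)  # 4*4 minus one centering constraint
        assert len(pens) == 2

    def test_smooth_blocks_are_centered(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame({"x": rng.uniform(0, 24, 200)})
        X, _ = wg.build_basis(
            gam.BasisSpec("cyclic", ("x",), k=8, period=(0, 24)), data
        )
        assert np.allclose(X.sum(axis=0), 0.0, atol=1e-8)


class TestFitting:
    def test_intercept_only_matches_closed_form(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.poisson(2.0, 200)})
        f = wg.fit(gam.ModelSpec("y"), df)
        assert f.beta[0] == pytest.approx(np.log(df.y.mean()), abs=1e-8)
        assert f.deviance_explained == pytest.approx(0.0, abs=1e-10)

    def test_infinite_smoothing_collapses_to_null_space_glm(self):
        """λ → ∞ on a natural cubic smooth leaves its linear null space: the
        fit matches a plain Poisson GLM in x."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 300)
        y = rng.poisson(np.exp(0.1 + 0.15 * x))
        df = pd.DataFrame({"y": y, "x": x})
        f = wg.fit(
            gam.ModelSpec("y", smooths=[gam.BasisSpec("cubic", ("x",), k=8)]),
            df,
            lambdas=np.array([1e12]),
        )
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert np.allclose(f.predict(df), glm.mu, rtol=1e-4)

    def test_pirls_matches_penalized_least_squares_oracle(self):
        """At convergence with fixed λ, β̂ solves the weighted PLS problem on
        the working response."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 24, 250)
        y = rng.poisson(np.exp(0.5 * np.cos(2 * np.pi * x / 24)))
        df = pd.DataFrame({"y": y, "x": x})
        spec = gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("x",), k=8, period=(0, 24))])
        f = wg.fit(spec, df, lambdas=np.array([2.5]))
        X = f.design.X
        S = 2.5 * f.design.penalties[0][1]
        eta = X @ f.beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        W = np.diag(mu)
        beta_pls = np.linalg.solve(X.T @ W @ X + S, X.T @ W @ z)
        assert np.allclose(f.beta, beta_pls, atol=1e-6)

    def test_fitted_deviance_below_null(self, study_fit):
        assert study_fit.deviance <= study_fit.null_deviance
        assert 0.0 <= study_fit.deviance_explained <= 1.0

    def test_thinplate_fit_equivariant_to_scaling(self):
        """Rescaling x (with λ rescaled by the cubed factor) leaves predictions
        unchanged: the radial basis spans the same function space."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 300)
        y = rng.poisson(np.exp(0.4 * np.sin(x)))
        d1 = pd.DataFrame({"y": y, "x": x})
        d2 = pd.DataFrame({"y": y, "x": 10.0 * x})
        spec = gam.ModelSpec("y", smooths=[gam.BasisSpec("thinplate", ("x",), k=8)])
        lam = 3.0
        f1 = wg.fit(spec, d1, lambdas=np.array([lam]))
        f2 = wg.fit(spec, d2, lambdas=np.array([lam]))
        assert np.allclose(f1.predict(d1), f2.predict(d2), atol=1e-6, rtol=1e-6)

    def test_parameter_recovery_on_cyclic_truth(self):
        """Fitted smooth correlates with the generating effect at r > 0.9."""
        rng = np.random.default_rng(4)
        n = 640
        h = rng.uniform(0, 24, n)
        truth = 0.8 * np.cos(2 * np.pi * (h - 5) / 24)
        y = rng.poisson(np.exp(-0.2 + truth))
        df = pd.DataFrame({"y": y, "h": h})
        f = wg.fit(
            gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("h",), k=10, period=(0, 24))]),
            df,
        )
        grid = pd.DataFrame({"h": np.linspace(0, 24, 200, endpoint=False)})
        eff, _ = f.term_effect("s(h)", grid)
        tgrid = 0.8 * np.cos(2 * np.pi * (grid.h - 5) / 24)
        assert np.corrcoef(eff, tgrid - tgrid.mean())[0, 1] > 0.9

    def test_non_integer_response_rejected(self):
        df = pd.DataFrame({"y": [0.5, 1.2, 3.0]})
        with pytest.raises(ValidationError):
            wg.fit(gam.ModelSpec("y"), df)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestAgainstMgcv:
    def test_reml_fit_matches_mgcv(self, tmp_path):
        """Fitted means agree with mgcv's REML Poisson GAM on the same data."""
        rng = np.random.default_rng(42)
        n = 300
        h = rng.uniform(0, 24, n)
        x = rng.uniform(0, 10, n)
        eta = -0.2 + 0.8 * np.cos(2 * np.pi * (h - 5) / 24) + 0.5 * np.sin(x / 10 * 2 * np.pi)
        y = rng.poisson(np.exp(eta))
        df = pd.DataFrame({"y": y, "h": h, "x": x})
        fin = tmp_path / "d.csv"
        fout = tmp_path / "mu.csv"
        df.to_csv(fin, index=False)
        r_code = f"""
        library(mgcv)
        d <- read.csv("{fin}")
        m <- gam(y ~ s(h, bs="cc", k=8) + s(x, bs="cr", k=8), data=d,
                 family=poisson(), method="REML",
                 knots=list(h=seq(0, 24, length=8)))
        write.csv(data.frame(mu=fitted(m), de=summary(m)$dev.expl),
                  "{fout}", row.names=FALSE)
        """
        res = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(fout)
        spec = gam.ModelSpec(
            "y",
            smooths=[
                gam.BasisSpec("cyclic", ("h",), k=8, period=(0, 24)),
                gam.BasisSpec("cubic", ("x",), k=8),
            ],
        )
        f = wg.fit(spec, df)
        mu = f.predict(df)
        assert np.corrcoef(mu, ref["mu"])[0, 1] > 0.999
        assert f.deviance_explained == pytest.approx(ref["de"].iloc[0], abs=0.01)


class TestDevianceDecomposition:
    def test_none_term_zero_share(self, study_fit):
        assert gam.deviance_decomposition(study_fit, "none")["share"] == 0.0

    def test_single_smooth_exclusion_matches_refit_oracle(self):
        """Zeroing the only smooth leaves ≈ the intercept-only explained
        deviance (0)."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 24, 400)
        y = rng.poisson(np.exp(0.6 * np.cos(2 * np.pi * x / 24)))
        df = pd.DataFrame({"y": y, "x": x})
        f = wg.fit(
            gam.ModelSpec("y", smooths=[gam.BasisSpec("cyclic", ("x",), k=8, period=(0, 24))]),
            df,
        )
        d = gam.deviance_decomposition(f, "s(x)")
        assert d["dev_explained_excluded"] == pytest.approx(0.0, abs=0.05)
        assert d["share"] == pytest.approx(1.0, rel=0.1)

    def test_unknown_term_rejected(self, study_fit):
        with pytest.raises(ValidationError):
            gam.deviance_decomposition(study_fit, "s(bogus)")

    def test_shares_sum_near_total(self, study_fit):
        shares = [
            gam.deviance_decomposition(study_fit, t)["share"]
            for t in study_fit.design.term_slices
            if t != "(Intercept)"
        ]
        assert all(s > -0.05 for s in shares)


class TestAICWeights:
    def test_equal_aics_split_evenly(self):
        assert np.allclose(wg.aic_weights([100.0, 100.0]), [0.5, 0.5])

    def test_delta_two_ratio(self):
        w = wg.aic_weights([10.0, 12.0])
        assert w[0] == pytest.approx(0.731, abs=1e-3)
        assert w[1] == pytest.approx(0.269, abs=1e-3)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        w = wg.aic_weights(rng.uniform(500, 600, 17))
        assert w.sum() == pytest.approx(1.0)


class TestForwardSelection:
    @staticmethod
    def _data(seed, n=500, signal=True):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 24, n)
        z1 = rng.uniform(0, 1, n)
        z2 = rng.uniform(0, 1, n)
        eta = -0.2 + (0.9 * np.cos(2 * np.pi * (x - 5) / 24) if signal else 0.0)
        return pd.DataFrame({"y": rng.poisson(np.exp(eta)), "x": x, "z1": z1, "z2": z2})

    @staticmethod
    def _candidates():
        return [
            gam.BasisSpec("cyclic", ("x",), k=8, period=(0, 24)),
            gam.BasisSpec("cubic", ("z1",), k=6),
            gam.BasisSpec("cubic", ("z2",), k=6),
        ]

    def test_true_driver_selected_first(self):
        df = self._data(0)
        trace = wg.forward_select(self._candidates(), gam.ModelSpec("y"), df)
        kept = trace.to_frame().query("kept")
        assert kept.iloc[0]["candidate"] == "s(x)"

    def test_pure_noise_rarely_enters(self):
        """With only noise candidates the base model survives in ≥90% of runs."""
        empty = 0
        runs = 50
        for seed in range(runs):
            df = self._data(seed, n=500, signal=False)
            trace = wg.forward_select(
                self._candidates()[1:], gam.ModelSpec("y"), df, maxfev=60
            )
            empty += not trace.to_frame()["kept"].any()
        assert empty / runs >= 0.9

    def test_weights_sum_to_one_each_round(self):
        df = self._data(1)
        trace = wg.forward_select(self._candidates(), gam.ModelSpec("y"), df).to_frame()
        for _, grp in trace.groupby("round"):
            finite = grp[np.isfinite(grp["aic"])]
            assert finite["weight"].sum() == pytest.approx(1.0, abs=1e-8)
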