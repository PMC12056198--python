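"""Spline basis, penalized IRLS, smoothing selection, prediction, Moran's I."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from _reference import intercept_management_fit, morans_i_brute
from firematch.gam import (
    GamSpec,
    build_design,
    fit_pirls,
    morans_i,
    predict_burn_prob,
    select_smoothing,
)
from firematch.splines import SplineBasisSpec, cr_basis, cr_knots, sum_to_zero


def _smooth_only_table(x, y=None, name="elevation"):
    df = pd.DataFrame({name: x})
    if y is not None:
        df["burned"] = y
    return df


SMOOTH_ONLY = GamSpec(
    covariates=("elevation",), coord_smooths=False, management_term=False,
    random_intercepts=(), interactions=(),
)
PARAMETRIC_ONLY = GamSpec(
    covariates=(), coord_smooths=False, random_intercepts=(), interactions=()
)


class TestCrBasis:
    def test_interpolates_knot_values(self):
        knots = np.array([0.0, 1.0, 2.5, 4.0])
        spec = SplineBasisSpec("x", knots, k=4)
        B, _ = cr_basis(knots, spec)
        np.testing.assert_allclose(B, np.eye(4), atol=1e-12)

    def test_centering_removes_one_column(self):
        x = np.random.default_rng(0).normal(size=200)
        spec = SplineBasisSpec("x", cr_knots(x, 10), k=10)
        B, S = cr_basis(x, spec)
        Bc, Sc, Z = sum_to_zero(B, S)
        assert B.shape[1] == 10 and Bc.shape[1] == 9
        assert abs(Bc.sum()) < 1e-8  # columns sum to zero over the data

    def test_penalty_annihilates_linear_functions(self):
        knots = np.linspace(-2, 2, 8)
        spec = SplineBasisSpec("x", knots, k=8)
        _, S = cr_basis(knots, spec)
        beta_lin = 0.7 + 1.3 * knots  # a linear function's knot values
        assert float(beta_lin @ S @ beta_lin) == pytest.approx(0.0, abs=1e-10)
        beta_quad = knots**2
        assert float(beta_quad @ S @ beta_quad) > 1e-6

    def test_matches_reference_smoothing_spline(self):
        """Penalized regression with knots at the data equals the classical
        smoothing spline (independent implementation) on a 50-point toy fit."""
        from scipy.interpolate import make_smoothing_spline

        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 10, 50))
        y = np.sin(x) + 0.3 * rng.normal(size=50)
        lam = 0.5
        spec = SplineBasisSpec("x", x, k=50)
        B, S = cr_basis(x, spec)
        beta = np.linalg.solve(B.T @ B + lam * S, B.T @ y)
        ours = B @ beta
        ref = make_smoothing_spline(x, y, lam=lam)(x)
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_linear_extrapolation_warns(self):
        knots = np.linspace(0, 1, 5)
        spec = SplineBasisSpec("x", knots, k=5)
        with pytest.warns(UserWarning, match="extrapolating"):
            B, _ = cr_basis(np.array([-1.0, 0.5, 2.0]), spec)
        # extrapolated rows still reproduce a linear function exactly
        beta_lin = 2.0 + 3.0 * knots
        np.testing.assert_allclose(
            B @ beta_lin, 2.0 + 3.0 * np.array([-1.0, 0.5, 2.0]), atol=1e-10
        )


class TestBuildDesign:
    def _table(self, n=60, n_biomes=2, n_countries=3, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "biome": rng.choice([f"b{i}" for i in range(n_biomes)], n),
                "country": rng.choice([f"c{i}" for i in range(n_countries)], n),
                "mgmt_class": rng.choice(
                    ["plantation_temperate", "natural_production"], n
                ),
                "burned": rng.integers(0, 2, n),
            }
        )
        from firematch.synthetic import COVARIATES

        for name in COVARIATES + ["lon", "lat"]:
            df[name] = rng.normal(size=n)
        return df

    def test_biome_country_block_combinatorics(self):
        pts = self._table()
        d = build_design(pts, GamSpec(k=4))
        block = next(b for b in d.blocks if b.name == "biome:country")
        assert block.n_cols == 6  # all 2×3 observed combinations, ridge-penalized

    def test_ablation_without_interactions(self):
        pts = self._table()
        d = build_design(pts, GamSpec(k=4, interactions=()))
        kinds = {b.kind for b in d.blocks}
        assert kinds == {"parametric", "smooth", "random"}

    def test_columns_partition_into_terms(self):
        pts = self._table()
        d = build_design(pts, GamSpec(k=4))
        covered = np.zeros(d.n_params, dtype=int)
        for b in d.blocks:
            covered[b.sl] += 1
        assert (covered == 1).all()

    def test_unseen_level_raises_at_predict(self):
        pts = self._table()
        d = build_design(pts, GamSpec(k=4))
        fit = fit_pirls(d, pts["burned"].to_numpy(float), 1.0)
        bad = pts.copy()
        bad.loc[0, "country"] = "atlantis"
        with pytest.raises(ValueError, match="atlantis"):
            predict_burn_prob(fit, bad)


class TestFitPirls:
    def test_intercept_only_closed_form(self):
        n = 80
        y = np.zeros(n)
        y[: n // 4] = 1.0
        df = _smooth_only_table(np.zeros(n), y)
        spec = GamSpec(covariates=(), coord_smooths=False, management_term=False,
                       random_intercepts=(), interactions=())
        d = build_design(df, spec)
        fit = fit_pirls(d, y)
        assert fit.coefficients[0] == pytest.approx(logit(0.25), abs=1e-8)

    def test_zero_penalty_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 400
        mgmt = rng.random(n) < 0.5
        eta = -1.0 + 0.8 * mgmt
        y = (rng.random(n) < expit(eta)).astype(float)
        df = pd.DataFrame(
            {"mgmt_class": np.where(mgmt, "plantation_temperate", "natural_production")}
        )
        d = build_design(df, PARAMETRIC_ONLY)
        fit = fit_pirls(d, y, {})
        ref = sm.GLM(y, np.column_stack([np.ones(n), mgmt]),
                     family=sm.families.Binomial()).fit(tol=1e-12)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)

    def test_huge_lambda_collapses_smooth_to_linear(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(np.sin(2 * x))).astype(float)
        df = _smooth_only_table(x, y)
        d = build_design(df, SMOOTH_ONLY)
        fit = fit_pirls(d, y, 1e12)
        block = next(b for b in d.blocks if b.name == "s(elevation)")
        contrib = d.X[:, block.sl] @ fit.coefficients[block.sl]
        # contribution must lie in the span of {1, x}
        A = np.column_stack([np.ones(n), x])
        resid = contrib - A @ np.linalg.lstsq(A, contrib, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-6
        assert fit.edf["s(elevation)"] == pytest.approx(1.0, abs=0.01)

    def test_score_equation_and_edf_bounds(self):
        rng = np.random.default_rng(7)
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + np.tanh(x))).astype(float)
        df = _smooth_only_table(x, y)
        d = build_design(df, SMOOTH_ONLY)
        fit = fit_pirls(d, y, 1.0)
        assert fit.converged
        # unpenalized intercept ⇒ fitted probabilities sum to observed burns
        assert abs(fit.fitted.sum() - y.sum()) < 1e-6 * n
        for b in d.blocks:
            assert b.null_dim() - 1e-8 <= fit.edf[b.name] <= b.n_cols + 1e-8

    def test_rejects_nonbinary_response(self):
        df = _smooth_only_table(np.linspace(-1, 1, 40), np.linspace(0, 1, 40))
        d = build_design(df, SMOOTH_ONLY)
        with pytest.raises(ValueError, match="binary"):
            fit_pirls(d, df["burned"].to_numpy())


class TestSelectSmoothing:
    def _fit_truth(self, f, n=2000, seed=4):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(f(x))).astype(float)
        df = _smooth_only_table(x, y)
        d = build_design(df, SMOOTH_ONLY)
        lam, fit = select_smoothing(d, y)
        return fit

    def test_linear_truth_selects_small_edf(self):
        fit = self._fit_truth(lambda x: -0.3 + 1.2 * x)
        assert fit.edf["s(elevation)"] <= 2.5

    def test_sinusoidal_truth_selects_large_edf(self):
        fit = self._fit_truth(lambda x: 2.0 * np.sin(2.5 * x))
        assert fit.edf["s(elevation)"] >= 4.0

    def test_grid_refinement_is_stable(self):
        rng = np.random.default_rng(4)
        n = 800
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(np.tanh(2 * x))).astype(float)
        df = _smooth_only_table(x, y)
        d = build_design(df, SMOOTH_ONLY)
        _, fit_coarse = select_smoothing(d, y)
        _, fit_fine = select_smoothing(d, y, sweeps=4)
        gcv = lambda f: n * f.deviance / (n - f.edf_total) ** 2
        assert abs(gcv(fit_fine) - gcv(fit_coarse)) / gcv(fit_coarse) < 0.01


class TestPredict:
    def test_hand_built_fit_closed_form(self):
        fit = intercept_management_fit(-2.0, 1.0)
        pts = pd.DataFrame({"mgmt_class": ["natural_production"] * 3})
        np.testing.assert_allclose(
            predict_burn_prob(fit, pts, "natural_production"), expit(-2.0), atol=1e-9
        )
        np.testing.assert_allclose(
            predict_burn_prob(fit, pts, "plantation"), expit(-1.0), atol=1e-9
        )

    def test_no_override_reproduces_fitted(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.3).astype(float)
        df = _smooth_only_table(x, y)
        d = build_design(df, SMOOTH_ONLY)
        fit = fit_pirls(d, y, 1.0)
        np.testing.assert_allclose(predict_burn_prob(fit, df), fit.fitted, atol=1e-12)

    def test_probability_range_and_row_order_invariance(self):
        rng = np.random.default_rng(10)
        n = 500
        df = _smooth_only_table(rng.normal(size=n), (rng.random(n) < 0.2).astype(float))
        d = build_design(df, SMOOTH_ONLY)
        fit = fit_pirls(d, df["burned"].to_numpy(), 1.0)
        p = predict_burn_prob(fit, df)
        assert np.all((p > 0) & (p < 1))
        perm = rng.permutation(n)
        p_perm = predict_burn_prob(fit, df.iloc[perm])
        np.testing.assert_allclose(p_perm, p[perm], atol=1e-12)


def test_save_diagnostics_writes_variogram(tmp_path):
    from firematch.gam import fit_pirls as _fp, save_diagnostics

    rng = np.random.default_rng(2)
    n = 120
    df = _smooth_only_table(rng.normal(size=n), (rng.random(n) < 0.3).astype(float))
    df["lon"] = rng.uniform(0, 2, n)
    df["lat"] = rng.uniform(40, 42, n)
    d = build_design(df, SMOOTH_ONLY)
    fit = _fp(d, df["burned"].to_numpy(), 1.0)
    table = save_diagnostics(fit, df, str(tmp_path / "gam"), n_bins=8)
    assert (tmp_path / "gam_variogram.csv").exists()
    assert (tmp_path / "gam_diagnostics.png").exists()
    assert (table["semivariance"] >= 0).all()
    assert table["n_pairs"].sum() <= n * (n - 1) // 2


class TestMoransI:
    def test_null_expectation_formula(self):
        rng = np.random.default_rng(1)
        n = 30
        _, expected, _ = morans_i(rng.normal(size=n), rng.uniform(size=n),
                                  rng.uniform(size=n), n_perm=19)
        assert expected == pytest.approx(-1.0 / (n - 1))

    def test_checkerboard_is_negatively_autocorrelated(self):
        g = np.arange(8)
        lon, lat = np.meshgrid(g, g)
        lon, lat = lon.ravel().astype(float), lat.ravel().astype(float)
        values = ((lon + lat) % 2 * 2 - 1).astype(float)
        I, expected, p = morans_i(values, lon, lat, k_neighbors=4, n_perm=999, seed=0)
        assert I < expected
        assert p < 0.05

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(3)
        n = 60
        lon, lat = rng.uniform(0, 5, n), rng.uniform(0, 5, n)
        v = np.sin(lon) + rng.normal(scale=0.3, size=n)
        I, _, _ = morans_i(v, lon, lat, k_neighbors=8, n_perm=19)
        assert I == pytest.approx(morans_i_brute(v, lon, lat, 8), abs=1e-12)

    def test_type_one_error_calibrated(self):
        """i.i.d. residuals: the permutation test rejects ≈5% of the time."""
        rng = np.random.default_rng(4)
        n = 100
        lon, lat = rng.uniform(0, 5, n), rng.uniform(0, 5, n)
        rejections = 0
        for rep in range(100):
            v = rng.normal(size=n)
            _, _, p = morans_i(v, lon, lat, n_perm=499, seed=rep)
            rejections += p < 0.05
        assert rejections <= 11  # 5% nominal + 3 binomial SE

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(40), np.arange(40.0), np.arange(40.0))
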