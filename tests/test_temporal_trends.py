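"""Annual correlations, per-pixel trend GLMs and the area-change model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fireregime import temporal_trends as tt
from fireregime.grids import Grid, Raster


def stack_from(arr3d, years=None):
    """dict year -> Raster from a (n_years, nr, nc) array."""
    years = years or list(range(2001, 2001 + arr3d.shape[0]))
    grid = Grid(nrows=arr3d.shape[1], ncols=arr3d.shape[2], cell_size=6000.0)
    return {y: Raster(grid, arr3d[i]) for i, y in enumerate(years)}


class TestAnnualCorrelations:
    def _series(self, n=14, rng=None):
        rng = rng or np.random.default_rng(0)
        year = np.arange(2001, 2001 + n)
        return pd.DataFrame({
            "year": year,
            "n_fires": rng.integers(400, 1500, n).astype(float),
            "area_burnt_km2": rng.uniform(2000, 13000, n),
            "median_size_top_decile": rng.uniform(5, 50, n),
            "median_ignition_day": rng.uniform(100, 250, n),
            "median_tslf_years": rng.uniform(1, 5, n),
            "median_frp": rng.uniform(5, 20, n),
        })

    def test_exactly_linear_series_r_one(self):
        df = self._series()
        df["n_fires"] = 100.0 + 3.0 * (df["year"] - 2001)
        out = tt.annual_correlations(df).set_index("test")
        row = out.loc["n_fires_vs_year"]
        assert row["r"] == pytest.approx(1.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_df_convention_fourteen_years_gives_twelve(self):
        out = tt.annual_correlations(self._series(n=14))
        assert (out["df"] == 12).all()

    def test_constant_series_flagged(self):
        df = self._series()
        df["median_frp"] = 7.0
        out = tt.annual_correlations(df).set_index("test")
        assert bool(out.loc["median_frp_vs_year", "constant"])
        assert np.isnan(out.loc["median_frp_vs_year", "r"])

    def test_type_one_error_near_nominal(self):
        # independent noise at n=14: the year test should reject ~5%
        rng = np.random.default_rng(99)
        n_rej, reps = 0, 2000
        year = np.arange(14, dtype=float)
        from scipy import stats

        for _ in range(reps):
            y = rng.normal(size=14)
            _, p = stats.pearsonr(y, year)
            n_rej += p < 0.05
        rate = n_rej / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestPerPixelTrend:
    def test_gaussian_equals_closed_form_ols(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(0, 30, size=(14, 6, 6))
        trend = tt.per_pixel_trend(stack_from(arr), family="gaussian")
        t = np.arange(14, dtype=float)
        for r in range(6):
            for c in range(6):
                y = arr[:, r, c]
                want = np.polyfit(t, y, 1)
                assert trend.slope.data[r, c] == pytest.approx(want[0], abs=1e-10)
                assert trend.baseline.data[r, c] == pytest.approx(want[1], abs=1e-10)

    def test_constant_cell_zero_slope(self):
        arr = np.full((10, 3, 3), 4.2)
        trend = tt.per_pixel_trend(stack_from(arr))
        np.testing.assert_allclose(trend.slope.data, 0.0, atol=1e-12)

    def test_poisson_log_linear_recovery(self):
        rng = np.random.default_rng(6)
        t = np.arange(14)
        lam = 20 * np.exp(0.05 * t)
        arr = rng.poisson(lam[:, None, None], size=(14, 4, 4)).astype(float)
        trend = tt.per_pixel_trend(stack_from(arr), family="poisson")
        assert trend.slope.data.mean() == pytest.approx(0.05, abs=0.015)
        assert trend.baseline.data.mean() == pytest.approx(20, rel=0.15)

    def test_cells_with_too_few_years_missing(self):
        arr = np.full((5, 2, 2), 3.0)
        arr[:, 0, 0] = np.nan
        arr[0, 0, 0] = 1.0
        trend = tt.per_pixel_trend(stack_from(arr))
        assert np.isnan(trend.slope.data[0, 0])
        assert np.isfinite(trend.slope.data[1, 1])


def synth_cells(rng, n=200, beta_boma=0.0, noise=1.0):
    units = rng.choice(["a", "b", "c"], size=n)
    unit_eff = {"a": 0.0, "b": 0.5, "c": -0.5}
    df = pd.DataFrame({
        "boma_rate": rng.normal(0, 1, n),
        "rain_mean": rng.normal(0, 1, n),
        "rain_trend": rng.normal(0, 1, n),
        "baseline": rng.normal(0, 1, n),
        "unit": units,
    })
    df["response"] = (
        beta_boma * df["boma_rate"]
        + np.array([unit_eff[u] for u in units]) * 0.0
        + rng.normal(0, noise, n)
    )
    return df


class TestAreaChangeModel:
    def test_planted_boma_effect_retained_negative(self):
        rng = np.random.default_rng(7)
        df = synth_cells(rng, beta_boma=-2.0, noise=0.5)
        fit = tt.area_change_model(df)
        assert "boma_rate" in fit.formula_reduced
        assert fit.reduced.params["boma_rate"] < 0

    def test_pure_noise_reduces_toward_null(self):
        hits = 0
        for seed in range(20):
            df = synth_cells(np.random.default_rng(100 + seed))
            fit = tt.area_change_model(df)
            # count retained optional terms (interactions + mains + factor)
            hits += len(tt._terms_of(fit.formula_reduced))
        # on average almost everything is removed under the null
        assert hits / 20 < 1.5

    def test_reduced_model_nested_with_higher_deviance(self):
        rng = np.random.default_rng(8)
        df = synth_cells(rng, beta_boma=-1.0)
        fit = tt.area_change_model(df)
        assert fit.reduced.deviance >= fit.full.deviance - 1e-9
        assert fit.reduced.df_model <= fit.full.df_model

    def test_marginality_respected_in_deletion_path(self):
        rng = np.random.default_rng(9)
        df = synth_cells(rng, beta_boma=-3.0, noise=0.3)
        # force an interaction to matter
        df["response"] += 2.0 * df["boma_rate"] * df["rain_mean"]
        fit = tt.area_change_model(df)
        terms = tt._terms_of(fit.formula_reduced)
        if "boma_rate:rain_mean" in terms:
            assert "boma_rate" in terms and "rain_mean" in terms


class TestLrt:
    def test_gaussian_lrt_matches_independent_ols_deviances(self):
        rng = np.random.default_rng(11)
        n = 120
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 1.0 + 0.5 * x1 + rng.normal(size=n)
        Xf = sm.add_constant(np.column_stack([x1, x2]))
        Xr = sm.add_constant(x1)
        full = sm.GLM(y, Xf, family=sm.families.Gaussian()).fit()
        red = sm.GLM(y, Xr, family=sm.families.Gaussian()).fit()
        phi = full.pearson_chi2 / full.df_resid
        stat, ddf, p = tt.lrt(full, red, phi)
        # oracle: residual sums of squares from plain least squares
        rss_f = np.sum((y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]) ** 2)
        rss_r = np.sum((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2)
        want = (rss_r - rss_f) / (rss_f / (n - 3))
        assert stat == pytest.approx(want, rel=1e-10)
        assert ddf == 1


class TestTukey:
    def _fit(self, shift, rng, n=120):
        unit = np.repeat(["a", "b", "c"], n // 3)
        y = rng.normal(0, 1, n)
        y[unit == "c"] += shift
        df = pd.DataFrame({"response": y, "unit": unit})
        import statsmodels.formula.api as smf

        return smf.glm("response ~ C(unit)", data=df).fit(), df.rename(
            columns={"unit": "unit"})

    def test_identical_groups_p_near_one(self):
        fit, df = self._fit(0.0, np.random.default_rng(13))
        out = tt.tukey_hsd(fit, df, factor="unit")
        assert (out["p_adj"] > 0.2).all()

    def test_shifted_group_detected_only_in_its_contrasts(self):
        fit, df = self._fit(5.0, np.random.default_rng(14))
        out = tt.tukey_hsd(fit, df, factor="unit").set_index(["level_a", "level_b"])
        assert out.loc[("a", "c"), "p_adj"] < 0.001
        assert out.loc[("b", "c"), "p_adj"] < 0.001
        assert out.loc[("a", "b"), "p_adj"] > 0.05

    def test_adjusted_p_at_least_unadjusted(self):
        fit, df = self._fit(1.0, np.random.default_rng(15))
        out = tt.tukey_hsd(fit, df, factor="unit")
        assert (out["p_adj"] >= out["p_unadjusted"] - 1e-12).all()

    def test_missing_factor_informative_error(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({"response": rng.normal(size=30), "x": rng.normal(size=30)})
        import statsmodels.formula.api as smf

        fit = smf.glm("response ~ x", data=df).fit()
        with pytest.raises(ValueError, match="dropped|not in the fitted"):
            tt.tukey_hsd(fit, df, factor="unit")


class TestOverdispersion:
    def _poisson_fit(self, y, x):
        X = sm.add_constant(x)
        return sm.GLM(y, X, family=sm.families.Poisson()).fit()

    def test_poisson_data_near_one(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=500)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        out = tt.overdispersion_check(self._poisson_fit(y, x))
        assert out["dispersion"] == pytest.approx(1.0, abs=0.25)
        assert not out["overdispersed"]

    def test_negative_binomial_data_flagged(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=500)
        mu = np.exp(1.5 + 0.3 * x)
        y = rng.negative_binomial(1, 1 / (1 + mu))
        out = tt.overdispersion_check(self._poisson_fit(y, x))
        assert out["dispersion"] > 1.5
        assert out["overdispersed"]

    def test_zero_variance_response_below_one(self):
        y = np.full(60, 5)
        out = tt.overdispersion_check(self._poisson_fit(y, np.zeros(60)))
        assert out["dispersion"] < 1.0


class TestChangeDecomposition:
    def _trend(self, data):
        grid = Grid(nrows=data.shape[0], ncols=data.shape[1], cell_size=6000.0)
        r = Raster(grid, data)
        return tt.TrendRaster(r, r, r, r)

    def test_identical_rasters_r_one(self):
        rng = np.random.default_rng(19)
        d = rng.normal(size=(8, 8))
        out = tt.change_decomposition(self._trend(d), self._trend(d), self._trend(d))
        np.testing.assert_allclose(out["r"], 1.0, atol=1e-9)
        assert (out["df"] == 62).all()

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(20)
        out = tt.change_decomposition(
            self._trend(rng.normal(size=(20, 20))),
            self._trend(rng.normal(size=(20, 20))),
            self._trend(rng.normal(size=(20, 20))))
        assert (out["r"].abs() < 0.15).all()

    def test_planted_coupling_sign(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=(15, 15))
        coupled = 0.8 * a + 0.2 * rng.normal(size=(15, 15))
        out = tt.change_decomposition(self._trend(a), self._trend(coupled),
                                      self._trend(-coupled)).set_index("test")
        assert out.loc["area_vs_size", "r"] > 0.5
        assert out.loc["area_vs_n_fires", "r"] < -0.5
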