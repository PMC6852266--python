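"""Temporal change in the fire regime.

Three layers of analysis:

* ecosystem-wide Pearson correlations of the annual series against year
  (and the diagnostic pairs: number of fires vs area burnt, top-decile
  fire size vs area burnt / number of fires), with df = n - 2;
* per-pixel trend GLMs on the coarse-grid yearly rasters — Gaussian for
  areas and medians (the slope equals the closed-form OLS slope),
  Poisson with log link for fire counts — giving a slope raster and a
  baseline (first-year prediction) raster;
* a Gaussian GLM explaining the per-cell change in burnt area from the
  boma-density trend, management unit, mean and trend of annual
  rainfall and the baseline burnt area, with the interactions
  boma_rate:rain_mean, boma_rate:baseline and rain_trend:rain_mean,
  reduced by single-term deletions under likelihood-ratio tests at
  alpha = 0.05 (deletions respect marginality: a main effect is not
  removable while one of its interactions is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .grids import Grid, Raster

ALPHA = 0.05


@dataclass
class TrendRaster:
    slope: Raster
    baseline: Raster
    se: Raster
    n_years: Raster


@dataclass
class ModelFit:
    full: object
    reduced: object
    formula_full: str
    formula_reduced: str
    deletion_path: list = field(default_factory=list)
    lrt_table: pd.DataFrame | None = None
    dispersion: float = float("nan")
    n_obs: int = 0


def annual_correlations(series: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of annual fire metrics.

    Each characteristic is tested against year; the classic pairwise
    series are included.  Constant series get NaN and a flag.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 years")
    year = series["year"].to_numpy(float)
    tests = {}
    for col in ("n_fires", "area_burnt_km2", "median_size_top_decile",
                "median_ignition_day", "median_tslf_years", "median_frp"):
        if col in series:
            tests[f"{col}_vs_year"] = (series[col].to_numpy(float), year)
    tests["n_fires_vs_area"] = (
        series["n_fires"].to_numpy(float), series["area_burnt_km2"].to_numpy(float))
    tests["top_decile_size_vs_area"] = (
        series["median_size_top_decile"].to_numpy(float),
        series["area_burnt_km2"].to_numpy(float))
    tests["top_decile_size_vs_n_fires"] = (
        series["median_size_top_decile"].to_numpy(float), series["n_fires"].to_numpy(float))

    rows = []
    for name, (a, b) in tests.items():
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            rows.append({"test": name, "r": np.nan, "r2": np.nan,
                         "df": max(len(a) - 2, 0), "p": np.nan, "constant": True})
            continue
        r, p = stats.pearsonr(a, b)
        rows.append({"test": name, "r": float(r), "r2": float(r**2),
                     "df": len(a) - 2, "p": float(p), "constant": False})
    return pd.DataFrame(rows)


def per_pixel_trend(
    yearly: dict[int, Raster],
    family: str = "gaussian",
    min_years: int = 3,
) -> TrendRaster:
    """Per-cell GLM of a characteristic against (year - first year).

    Gaussian slopes/intercepts come from the closed form; Poisson cells
    are fitted by IRLS with a log link, the slope reported as the
    log-linear rate and the baseline as the first-year prediction.
    Cells with fewer than ``min_years`` finite values are left missing.
    """
    years = sorted(yearly)
    grid = yearly[years[0]].grid
    stack = np.stack([yearly[y].data for y in years])
    t = np.asarray(years, float) - years[0]
    shape = stack.shape[1:]
    slope = np.full(shape, np.nan)
    base = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    nyr = np.isfinite(stack).sum(axis=0).astype(float)

    if family == "gaussian":
        import warnings

        tb = t[:, None, None]
        valid = np.isfinite(stack)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            warnings.filterwarnings("ignore", message="Degrees of freedom")
            n = valid.sum(axis=0)
            tm = np.where(valid, tb, np.nan)
            ym = stack
            tbar = np.nanmean(tm, axis=0)
            ybar = np.nanmean(ym, axis=0)
            st = np.nansum((tm - tbar) ** 2, axis=0)
            sxy = np.nansum((tm - tbar) * (ym - ybar), axis=0)
            sl = sxy / st
            ic = ybar - sl * tbar
            resid = np.where(valid, ym - (ic + sl * tm), np.nan)
            dfres = np.maximum(n - 2, 1)
            s2 = np.nansum(resid**2, axis=0) / dfres
            sl_se = np.sqrt(s2 / st)
        ok = n >= min_years
        slope[ok], base[ok], se[ok] = sl[ok], ic[ok], sl_se[ok]
    elif family == "poisson":
        for idx in np.ndindex(*shape):
            y = stack[(slice(None),) + idx]
            okm = np.isfinite(y)
            if okm.sum() < min_years:
                continue
            X = sm.add_constant(t[okm])
            try:
                fit = sm.GLM(y[okm], X, family=sm.families.Poisson()).fit()
            except Exception:
                continue
            slope[idx] = fit.params[1]
            base[idx] = np.exp(fit.params[0])
            se[idx] = fit.bse[1]
    else:
        raise ValueError("family must be 'gaussian' or 'poisson'")

    mk = lambda d, nm: Raster(grid, d, name=nm)
    return TrendRaster(mk(slope, "slope"), mk(base, "baseline"), mk(se, "se"), mk(nyr, "n_years"))


FULL_FORMULA = (
    "response ~ boma_rate + rain_mean + rain_trend + baseline + C(unit)"
    " + boma_rate:rain_mean + boma_rate:baseline + rain_trend:rain_mean"
)


def _terms_of(formula: str) -> list[str]:
    return [t.strip() for t in formula.split("~")[1].split("+")]


def _gaussian_dispersion(fit) -> float:
    return float(fit.pearson_chi2 / fit.df_resid)


def lrt(fit_full, fit_reduced, dispersion: float | None = None) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested GLMs via scaled deviance.

    Statistic = (deviance_reduced - deviance_full) / dispersion, chi^2
    with df equal to the parameter-count difference.  For one-parameter
    families (Poisson) the dispersion is 1.
    """
    ddf = int(fit_full.df_model - fit_reduced.df_model)
    phi = 1.0 if dispersion is None else dispersion
    stat = float((fit_reduced.deviance - fit_full.deviance) / phi)
    return stat, ddf, float(stats.chi2.sf(stat, ddf))


def area_change_model(
    data: pd.DataFrame,
    formula: str = FULL_FORMULA,
    family: str = "gaussian",
    alpha: float = ALPHA,
) -> ModelFit:
    """Fit and reduce the GLM for per-cell change in burnt area.

    ``data`` needs columns response, boma_rate, rain_mean, rain_trend,
    baseline, unit.  Backward elimination removes, at each step, the
    removable term with the largest LRT p-value above ``alpha``.
    """
    data = data.dropna().reset_index(drop=True)
    fam = sm.families.Gaussian() if family == "gaussian" else sm.families.Poisson()
    dispersion_needed = family == "gaussian"

    def fit(fml):
        return smf.glm(fml, data=data, family=fam).fit()

    full_fit = fit(formula)
    if full_fit.df_resid < 5:
        raise ValueError(
            f"too few complete cells ({len(data)}) for the full area-change model "
            f"({int(full_fit.df_model) + 1} parameters); enlarge the domain or "
            "coarsen less"
        )
    terms = _terms_of(formula)
    current = list(terms)
    current_fit = full_fit
    path, lrt_rows = [], []
    while True:
        removable = [t for t in current if _removable(t, current)]
        if not removable:
            break
        best = None
        for term in removable:
            reduced_terms = [t for t in current if t != term]
            fml = "response ~ " + (" + ".join(reduced_terms) if reduced_terms else "1")
            red_fit = fit(fml)
            phi = _gaussian_dispersion(current_fit) if dispersion_needed else None
            stat, ddf, p = lrt(current_fit, red_fit, phi)
            lrt_rows.append({"step": len(path), "term": term, "lrt_stat": stat,
                             "df": ddf, "p": p})
            if best is None or p > best[2]:
                best = (term, red_fit, p, fml)
        term, red_fit, p, fml = best
        if p <= alpha:
            break
        current = [t for t in current if t != term]
        current_fit = red_fit
        path.append({"dropped": term, "p": p, "formula": fml})

    reduced_formula = "response ~ " + (" + ".join(current) if current else "1")
    return ModelFit(
        full=full_fit,
        reduced=current_fit,
        formula_full=formula,
        formula_reduced=reduced_formula,
        deletion_path=path,
        lrt_table=pd.DataFrame(lrt_rows),
        dispersion=_gaussian_dispersion(full_fit) if dispersion_needed else 1.0,
        n_obs=len(data),
    )


def _removable(term: str, current: list[str]) -> bool:
    """Marginality: a main effect stays while any retained interaction uses it."""
    if ":" in term:
        return True
    for t in current:
        if ":" in t and term in t.split(":"):
            return False
    return True


def tukey_hsd(fit, data: pd.DataFrame, factor: str = "unit") -> pd.DataFrame:
    """Tukey HSD pairwise contrasts of a factor retained in a GLM fit.

    Uses the fitted coefficients and their covariance; adjusted p-values
    come from the studentized-range distribution with the residual df,
    so the familywise error rate is controlled.
    """
    names = list(fit.params.index)
    fac_terms = {n: n.split("[T.")[1].rstrip("]") for n in names if n.startswith(f"C({factor})[T.")}
    if not fac_terms:
        raise ValueError(
            f"factor {factor!r} is not in the fitted model (it may have been "
            "dropped during model reduction)"
        )
    levels = sorted(set(data[factor]))
    ref = [lv for lv in levels if lv not in fac_terms.values()]
    if len(ref) != 1:
        raise ValueError("could not identify the reference level")
    ref = ref[0]
    cov = fit.cov_params()
    k = len(levels)
    df_resid = float(fit.df_resid)

    def coef_var(level):
        if level == ref:
            return 0.0, None
        name = f"C({factor})[T.{level}]"
        return float(fit.params[name]), name

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            bi, ni = coef_var(levels[i])
            bj, nj = coef_var(levels[j])
            diff = bi - bj
            var = 0.0
            if ni:
                var += float(cov.loc[ni, ni])
            if nj:
                var += float(cov.loc[nj, nj])
            if ni and nj:
                var -= 2 * float(cov.loc[ni, nj])
            se = np.sqrt(max(var, 1e-300))
            q = abs(diff) / (se / np.sqrt(2))
            p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            p_raw = float(2 * stats.t.sf(abs(diff) / se, df_resid))
            rows.append({"level_a": levels[i], "level_b": levels[j], "diff": diff,
                         "se": se, "p_adj": min(p_adj, 1.0), "p_unadjusted": p_raw,
                         "significant": p_adj < ALPHA})
    return pd.DataFrame(rows)


def overdispersion_check(fit) -> dict:
    """Pearson chi^2 / df overdispersion test for a Poisson GLM."""
    X2 = float(fit.pearson_chi2)
    df = int(fit.df_resid)
    ratio = X2 / df
    p = float(stats.chi2.sf(X2, df))
    return {"dispersion": ratio, "chi2": X2, "df": df, "p_value": p,
            "overdispersed": p < ALPHA}


def change_decomposition(
    area_trend: TrendRaster,
    size_trend: TrendRaster,
    count_trend: TrendRaster,
) -> pd.DataFrame:
    """Correlations separating the two routes to burnt-area change.

    Pearson r between the per-cell rate of change in area burnt and the
    rates of change in (a) fire size and (b) number of fires, over cells
    where all three are defined; df = n_cells - 2.
    """
    a = area_trend.slope.data.ravel()
    rows = []
    for name, other in (("area_vs_size", size_trend), ("area_vs_n_fires", count_trend)):
        b = other.slope.data.ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            rows.append({"test": name, "r": np.nan, "r2": np.nan, "df": int(ok.sum()) - 2,
                         "p": np.nan})
            continue
        r, p = stats.pearsonr(a[ok], b[ok])
        rows.append({"test": name, "r": float(r), "r2": float(r**2),
                     "df": int(ok.sum()) - 2, "p": float(p)})
    return pd.DataFrame(rows)
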