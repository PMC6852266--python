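"""End-to-end orchestration on a synthetic landscape.

``run_all`` executes simulate -> delineate -> covariates -> summarize ->
bomas -> ud -> trends -> drivers, writing every stage's outputs under a
run directory together with a provenance manifest (parameters, seeds
and SHA-256 digests of every artifact).  All randomness flows from the
single configured seed, so a rerun with the same configuration is
digest-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boma_density, covariates, fire_events, regime_summary, synthetic
from . import spatial_drivers, temporal_trends, wildebeest_ud
from .grids import Raster, write_ascii_grid

try:
    import yaml
except ImportError:  # pragma: no cover
    yaml = None


@dataclass
class RunConfig:
    out_dir: str = "fireregime_run"
    seed: int = 0
    # landscape
    grid_nrows: int = 96
    grid_ncols: int = 96
    pixel_size_m: float = 500.0
    years: tuple[int, int] = (2001, 2014)
    # fires
    n_fires_per_year: int = 40
    mean_fire_pixels: int = 10
    fire_size_sigma: float = 1.2
    n_fires_poisson: bool = True
    max_gap_days: int = 5
    connectivity: int = 8
    # detections
    detection_prob: float = 0.21
    frp_scale: float = 10.0
    # rainfall
    rain_gradient: float = -4.0
    rain_trend: float = 3.0
    # bomas
    boma_slope: float = 0.05
    boma_base_density: float = 2.0
    boma_footprints: int = 80
    holdout_fraction: float = 0.25
    # wildebeest
    n_individuals: int = 3
    fixes_per_month: int = 120
    ud_sigma2: float = 50.0
    ud_exclusion: str = "cumulative_mass"
    # analysis
    cumulative_rain_mode: str = "prev_rainfall_year_start"
    coarse_cell_km: float = 6.0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        if yaml is None:
            raise RuntimeError("pyyaml is required to read config files")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(d["years"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def _static_surfaces(cfg: synthetic.LandscapeConfig, rng: np.random.Generator):
    """Deterministic elevation/slope/soil/NPP surfaces for the landscape."""
    grid = cfg.grid()
    rr, cc = np.meshgrid(np.arange(grid.nrows), np.arange(grid.ncols), indexing="ij")
    elev = 1400.0 + 0.02 * cc * grid.cell_size + 40.0 * np.sin(rr / 7.0)
    elev += rng.normal(0, 5.0, elev.shape)
    gy, gx = np.gradient(elev, grid.cell_size)
    slope_deg = np.degrees(np.arctan(np.hypot(gx, gy)))
    soil = (3 * cc // grid.ncols).astype(float)  # 3 soil classes, west to east
    npp = 800.0 - 4.0 * (cc * grid.cell_size / 1000.0) + rng.normal(0, 20.0, elev.shape)
    return {
        "elevation": Raster(grid, elev, name="elevation"),
        "slope": Raster(grid, slope_deg, name="slope"),
        "soil": Raster(grid, soil, name="soil"),
        "npp_annual": Raster(grid, npp, name="npp_annual"),
    }


def _units_geojson(units) -> dict:
    feats = []
    for u in units:
        geom = u.polygon.__geo_interface__
        feats.append({
            "type": "Feature",
            "properties": {"name": u.name, "livestock_permitted": u.livestock_permitted,
                           "fire_policy": u.fire_policy},
            "geometry": geom,
        })
    return {"type": "FeatureCollection", "features": feats}


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the provenance manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": {}}

    def record(stage, name, path):
        manifest["artifacts"][f"{stage}/{name}"] = _sha256(path)

    # --- simulate ------------------------------------------------------
    land = synthetic.LandscapeConfig(
        grid_nrows=config.grid_nrows, grid_ncols=config.grid_ncols,
        pixel_size_m=config.pixel_size_m, years=config.years, seed=config.seed,
    )
    grid = land.grid()
    records, truth = synthetic.generate_burn_history(
        land, config.n_fires_per_year, config.mean_fire_pixels,
        size_sigma=config.fire_size_sigma, n_fires_poisson=config.n_fires_poisson,
        rng=rng,
    )
    detections = synthetic.generate_active_fires(
        records, truth, grid, detection_prob=config.detection_prob,
        frp_scale=config.frp_scale, rng=rng,
    )
    rain = synthetic.generate_rainfall(
        land, west_east_gradient=config.rain_gradient, trend=config.rain_trend, rng=rng,
    )
    # livestock pressure rises west -> east (toward the communal side)
    xmin_, _, xmax_, _ = grid.extent

    def boma_base(x, y):
        return config.boma_base_density * (0.5 + 1.5 * (x - xmin_) / (xmax_ - xmin_))

    boma_obs, boma_fps, boma_truth = synthetic.generate_boma_observations(
        land, slope=config.boma_slope, footprint_count=config.boma_footprints,
        base_density=boma_base, rng=rng,
    )
    ud_year = min(land.years[0] + 5, land.years[1])
    months = [(ud_year, m) for m in range(1, 13)]
    traj, traj_truth = synthetic.generate_trajectories(
        n_individuals=config.n_individuals, sigma2=config.ud_sigma2, months=months,
        fixes_per_month=[config.fixes_per_month] * len(months),
        start_xy=((grid.extent[0] + grid.extent[2]) / 2, (grid.extent[1] + grid.extent[3]) / 2),
        bounds=grid.extent,
        rng=rng,
    )
    statics = _static_surfaces(land, rng)

    sim = out / "simulate"
    sim.mkdir(exist_ok=True)
    _write_csv(records, sim / "burn_records.csv")
    _write_csv(detections, sim / "detections.csv")
    _write_csv(boma_obs, sim / "boma_observations.csv")
    _write_csv(traj, sim / "trajectories.csv")
    with open(sim / "units.geojson", "w") as fh:
        json.dump(_units_geojson(land.units), fh, sort_keys=True)
    with open(sim / "truth.json", "w") as fh:
        json.dump({"n_true_fires": int(len(truth.fires)),
                   "boma_slope": config.boma_slope,
                   "rain_trend": config.rain_trend,
                   "ud_sigma2": config.ud_sigma2}, fh, sort_keys=True)
    for name in ("burn_records", "detections", "boma_observations", "trajectories"):
        record("simulate", name, sim / f"{name}.csv")
    record("simulate", "units", sim / "units.geojson")
    manifest["stages"]["simulate"] = {"n_records": int(len(records)),
                                      "n_true_fires": int(len(truth.fires))}

    # --- delineate -----------------------------------------------------
    events, labels = fire_events.delineate_fires(
        records, grid, detections=detections,
        max_gap_days=config.max_gap_days, connectivity=config.connectivity,
    )
    dl = out / "delineate"
    dl.mkdir(exist_ok=True)
    _write_csv(events, dl / "events.csv")
    record("delineate", "events", dl / "events.csv")
    manifest["stages"]["delineate"] = {"n_events": int(len(events))}

    # --- wildebeest UDs (needed by covariates) -------------------------
    uds = wildebeest_ud.monthly_population_uds(traj, grid, exclusion=config.ud_exclusion)
    udd = out / "ud"
    udd.mkdir(exist_ok=True)
    for (year, month), ras in sorted(uds.items()):
        p = udd / f"ud_{year}_{month:02d}.asc"
        write_ascii_grid(ras, p)
        record("ud", p.stem, p)
    manifest["stages"]["ud"] = {"n_months": len(uds)}

    ud_by_month = {m: ras for (_, m), ras in uds.items()}

    def utilization(x, y, ignition_day):
        from . import calendars as cal

        _, month = cal.year_month(ignition_day)
        total = 0.0
        for back in range(3):
            mm = (month - back - 1) % 12 + 1
            ras = ud_by_month.get(mm)
            if ras is None:
                return float("nan")
            total += ras.value_at(x, y) if ras.grid.contains(x, y) else 0.0
        return total

    # --- bomas ---------------------------------------------------------
    coarse_factor = int(round(config.coarse_cell_km * 1000 / config.pixel_size_m))
    coarse = grid.coarsen(coarse_factor)
    rate, density_by_year, local_trends = boma_density.boma_surfaces(
        boma_obs, land.units, coarse, land.year_list(),
    )
    bd = out / "bomas"
    bd.mkdir(exist_ok=True)
    write_ascii_grid(rate, bd / "boma_rate.asc")
    record("bomas", "boma_rate", bd / "boma_rate.asc")
    for year in (land.years[0], land.years[1]):
        p = bd / f"boma_density_{year}.asc"
        write_ascii_grid(density_by_year[year], p)
        record("bomas", p.stem, p)
    _write_csv(local_trends, bd / "footprint_trends.csv")
    record("bomas", "footprint_trends", bd / "footprint_trends.csv")

    # synthetic single-image counts for verification
    hold_rng = np.random.default_rng(config.seed + 1000)
    hold_rows = []
    for _ in range(40):
        r = int(hold_rng.integers(0, coarse.nrows))
        c = int(hold_rng.integers(0, coarse.ncols))
        x, y = coarse.centroid(r, c)
        year = int(hold_rng.choice(land.year_list()))
        dens = max(0.0, boma_base(x, y) + config.boma_slope * (year - land.years[0]))
        hold_rows.append({
            "x": float(x), "y": float(y), "year": year,
            "count": int(hold_rng.poisson(dens * coarse.cell_area_km2)),
            "area_km2": coarse.cell_area_km2, "straddles": False,
        })
    holdout = pd.DataFrame(hold_rows)
    verification = boma_density.verify_holdout(
        density_by_year, holdout, land.units,
        fraction=config.holdout_fraction, seed=config.seed,
    )
    with open(bd / "verification.json", "w") as fh:
        json.dump(verification, fh, sort_keys=True)
    record("bomas", "verification", bd / "verification.json")
    manifest["stages"]["bomas"] = verification

    # --- covariates ----------------------------------------------------
    cov = covariates.build_fire_covariates(
        events, rain, static_surfaces=statics, units=land.units,
        cumulative_mode=config.cumulative_rain_mode, utilization=utilization,
    )
    # boma density at the fire's location and year
    dens_vals = []
    for _, ev in events.iterrows():
        ras = density_by_year[int(ev["calendar_year"])]
        dens_vals.append(ras.value_at(ev["centroid_x"], ev["centroid_y"]))
    cov["boma_density"] = dens_vals
    cv = out / "covariates"
    cv.mkdir(exist_ok=True)
    _write_csv(cov, cv / "covariates.csv")
    record("covariates", "covariates", cv / "covariates.csv")
    manifest["stages"]["covariates"] = {"n_rows": int(len(cov))}

    # --- summarize -----------------------------------------------------
    study_area = grid.nrows * grid.ncols * grid.cell_area_km2
    annual = regime_summary.annual_series(events, study_area_km2=study_area)
    units_tbl = regime_summary.unit_summary(events, land.units, records, grid)
    rasters = regime_summary.rasterize_characteristic(
        events, records, labels, grid, cell_km=config.coarse_cell_km)
    unburnt_km2, unburnt_frac = regime_summary.unburnt_extent(records, grid)
    sm_dir = out / "summarize"
    sm_dir.mkdir(exist_ok=True)
    _write_csv(annual, sm_dir / "annual_series.csv")
    _write_csv(units_tbl, sm_dir / "unit_summary.csv")
    record("summarize", "annual_series", sm_dir / "annual_series.csv")
    record("summarize", "unit_summary", sm_dir / "unit_summary.csv")
    for year in (land.years[0], land.years[1]):
        p = sm_dir / f"area_burnt_{year}.asc"
        write_ascii_grid(rasters["area_burnt"][year], p)
        record("summarize", p.stem, p)
    manifest["stages"]["summarize"] = {
        "unburnt_km2": unburnt_km2, "unburnt_fraction": unburnt_frac,
    }

    # --- trends --------------------------------------------------------
    area_trend = temporal_trends.per_pixel_trend(rasters["area_burnt"], family="gaussian")
    count_trend = temporal_trends.per_pixel_trend(rasters["n_fires"], family="poisson")
    size_trend = temporal_trends.per_pixel_trend(rasters["median_size"], family="gaussian")
    corr = temporal_trends.annual_correlations(annual)

    rain_slope, rain_base = covariates.annual_rainfall_trend(rain)
    rr, cc = np.meshgrid(np.arange(coarse.nrows), np.arange(coarse.ncols), indexing="ij")
    gx, gy = coarse.centroid(rr.ravel(), cc.ravel())
    cell_unit, rain_mean_c, rain_trend_c = [], [], []
    n_years = len(land.year_list())
    for x, y in zip(gx, gy):
        from shapely.geometry import Point

        pt = Point(x, y)
        cell_unit.append(next((u.name for u in land.units if u.polygon.intersects(pt)), "none"))
        if rain_slope.grid.contains(x, y):
            r_, c_ = rain_slope.grid.cell_of(x, y)
            rain_trend_c.append(rain_slope.data[r_, c_])
            rain_mean_c.append(rain_base.data[r_, c_] + rain_slope.data[r_, c_] * (n_years - 1) / 2)
        else:
            rain_trend_c.append(np.nan)
            rain_mean_c.append(np.nan)
    cell_tbl = pd.DataFrame({
        "response": area_trend.slope.data.ravel(),
        "baseline": area_trend.baseline.data.ravel(),
        "boma_rate": rate.data.ravel(),
        "rain_mean": rain_mean_c,
        "rain_trend": rain_trend_c,
        "unit": cell_unit,
    })
    try:
        fit = temporal_trends.area_change_model(cell_tbl, alpha=config.alpha)
    except ValueError as err:
        fit = None
        area_change_note = f"skipped: {err}"
    else:
        area_change_note = "fitted"
    decomp = temporal_trends.change_decomposition(area_trend, size_trend, count_trend)

    tr = out / "trends"
    tr.mkdir(exist_ok=True)
    write_ascii_grid(area_trend.slope, tr / "area_burnt_slope.asc")
    record("trends", "area_burnt_slope", tr / "area_burnt_slope.asc")
    _write_csv(corr, tr / "annual_correlations.csv")
    record("trends", "annual_correlations", tr / "annual_correlations.csv")
    _write_csv(decomp, tr / "change_decomposition.csv")
    record("trends", "change_decomposition", tr / "change_decomposition.csv")
    manifest["stages"]["trends"] = {"area_change_model": area_change_note}
    if fit is not None:
        coef_tbl = pd.DataFrame({
            "term": fit.reduced.params.index,
            "coef": fit.reduced.params.to_numpy(),
            "se": fit.reduced.bse.to_numpy(),
        })
        _write_csv(coef_tbl, tr / "area_change_coefficients.csv")
        record("trends", "area_change_coefficients", tr / "area_change_coefficients.csv")
        manifest["stages"]["trends"].update(
            formula_reduced=fit.formula_reduced,
            n_cells=fit.n_obs,
            dispersion=fit.dispersion,
        )

    # --- drivers -------------------------------------------------------
    drv_data = events.merge(cov, on="event_id")
    drv_data["log_size"] = np.log(drv_data["size_km2"])
    X, yresp, info = spatial_drivers.build_design(
        drv_data, "log_size",
        continuous=("monthly_rain", "cumulative_rain", "boma_density",
                    "wildebeest_3mo", "slope", "elevation", "npp_annual"),
        categorical=("unit", "soil"),
    )
    coords = drv_data.loc[yresp.index, ["centroid_x", "centroid_y"]].to_numpy()
    dr = out / "drivers"
    dr.mkdir(exist_ok=True)
    try:
        sfit = spatial_drivers.fit_gmrf_regression(
            X, yresp, coords, mesh_cell=config.coarse_cell_km * 2000.0)
    except ValueError as err:
        manifest["stages"]["drivers"] = {"status": f"skipped: {err}"}
    else:
        support = spatial_drivers.report_support(sfit)
        _write_csv(sfit.summary().reset_index(names="term"), dr / "size_coefficients.csv")
        _write_csv(support, dr / "size_support.csv")
        record("drivers", "size_coefficients", dr / "size_coefficients.csv")
        record("drivers", "size_support", dr / "size_support.csv")
        manifest["stages"]["drivers"] = {
            "status": "fitted", "tau": sfit.tau, "sigma2": sfit.sigma2,
            "n_dropped_rows": info.n_dropped_rows,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
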