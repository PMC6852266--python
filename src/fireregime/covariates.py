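"""Per-fire and per-pixel covariates.

Rainfall enters the driver models at two time scales: rainfall in the
month of the fire (immediate moisture, suppressing fire) and rainfall
accumulated over the preceding rainfall year(s) (standing grass biomass,
i.e. fuel).  A rainfall year runs October-September and is labelled by
its ending September (Oct 2005 - Sep 2006 -> 2006).

The cumulative window is configurable because two natural readings
exist: from the start of the *previous* rainfall year (default), or one
rainfall year earlier still (``two_rainfall_years``).  Both windows end
with the month preceding ignition, so the monthly and cumulative
covariates never double-count the ignition month.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calendars as cal
from .calendars import rainfall_year  # re-exported: part of this module's surface
from .grids import Raster
from .synthetic import RainfallSeries

__all__ = [
    "rainfall_year",
    "monthly_rain_at",
    "cumulative_rain_at",
    "annual_rainfall_trend",
    "extract_static",
    "build_fire_covariates",
]


def monthly_rain_at(fire, series: RainfallSeries) -> float:
    """Rainfall (mm) in the fire's ignition month at its centroid cell."""
    x, y = _centroid(fire)
    year, month = cal.year_month(_ignition(fire))
    return series.value(year, month, x, y)


def cumulative_rain_at(fire, series: RainfallSeries, mode: str = "prev_rainfall_year_start") -> float:
    """Accumulated rainfall (mm) at the fire centroid before ignition.

    ``prev_rainfall_year_start`` sums from October opening the rainfall
    year before the fire's; ``two_rainfall_years`` starts one rainfall
    year earlier.  Both sums end at the month preceding ignition.
    """
    if mode not in ("prev_rainfall_year_start", "two_rainfall_years"):
        raise ValueError(f"unknown mode {mode!r}")
    back = 1 if mode == "prev_rainfall_year_start" else 2
    x, y = _centroid(fire)
    ignition = _ignition(fire)
    ry = cal.rainfall_year(ignition)
    start = cal.rainfall_year_start(ry - back)
    iy, im = cal.year_month(ignition)
    # end at the month before ignition
    ey, em = (iy, im - 1) if im > 1 else (iy - 1, 12)
    if cal.month_index(*start, series.start) < 0:
        raise ValueError("cumulative window precedes the rainfall series")
    total = 0.0
    for y_, m_ in cal.month_range(start, (ey, em)):
        total += series.value(y_, m_, x, y)
    return total


def annual_rainfall_trend(series: RainfallSeries) -> tuple[Raster, Raster]:
    """Per-pixel linear trend in annual rainfall.

    Fits a Gaussian GLM (ordinary least squares, which it equals) of
    annual total against year in every rainfall pixel; returns (slope,
    intercept) rasters where the intercept is the fitted value in the
    first year.
    """
    years = series.complete_years()
    if len(years) < 3:
        raise ValueError("need >= 3 complete years for a trend")
    stack = np.stack([series.annual_total(y) for y in years])
    t = np.asarray(years, dtype=float) - years[0]
    slope, intercept = _ols_stack(t, stack)
    return (
        Raster(series.grid, slope, name="annual_rainfall_slope"),
        Raster(series.grid, intercept, name="annual_rainfall_baseline", time=years[0]),
    )


def _ols_stack(t: np.ndarray, stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS slope/intercept of stack (n_t, ...) against t."""
    tbar = t.mean()
    ybar = stack.mean(axis=0)
    st = ((t - tbar) ** 2).sum()
    slope = np.tensordot(t - tbar, stack - ybar, axes=(0, 0)) / st
    intercept = ybar - slope * tbar
    return slope, intercept


def extract_static(fire, surface: Raster):
    """Value of a static covariate surface at the fire centroid cell.

    Returns ``np.nan`` for nodata holes (callers flag missingness).
    Categorical surfaces are stored as integer codes; decoding to labels
    is the caller's mapping.
    """
    x, y = _centroid(fire)
    if not surface.grid.contains(x, y):
        raise ValueError("fire centroid outside covariate surface")
    return surface.value_at(x, y)


def build_fire_covariates(
    events: pd.DataFrame,
    series: RainfallSeries,
    static_surfaces: dict[str, Raster] | None = None,
    units=None,
    cumulative_mode: str = "prev_rainfall_year_start",
    utilization=None,
) -> pd.DataFrame:
    """Assemble the per-fire covariate table keyed by event_id.

    ``units`` is a list of management units (centroid point-in-polygon
    assignment); ``utilization`` an optional callable mapping
    (x, y, ignition_day) to the 3-month cumulative utilization.
    Fires whose cumulative-rain window precedes the rainfall series get
    a missing cumulative value rather than an error.
    """
    from shapely.geometry import Point

    rows = []
    for _, ev in events.iterrows():
        rec: dict = {"event_id": int(ev["event_id"])}
        rec["monthly_rain"] = monthly_rain_at(ev, series)
        try:
            rec["cumulative_rain"] = cumulative_rain_at(ev, series, mode=cumulative_mode)
        except ValueError:
            rec["cumulative_rain"] = np.nan
        if static_surfaces:
            for nm, surf in static_surfaces.items():
                rec[nm] = extract_static(ev, surf)
        if units is not None:
            pt = Point(ev["centroid_x"], ev["centroid_y"])
            rec["unit"] = next((u.name for u in units if u.polygon.intersects(pt)), "none")
        if utilization is not None:
            rec["wildebeest_3mo"] = utilization(ev["centroid_x"], ev["centroid_y"], int(ev["ignition_date"]))
        rows.append(rec)
    return pd.DataFrame(rows)


def _centroid(fire) -> tuple[float, float]:
    if hasattr(fire, "centroid_xy"):
        return fire.centroid_xy
    return float(fire["centroid_x"]), float(fire["centroid_y"])


def _ignition(fire) -> int:
    if hasattr(fire, "ignition_date") and not isinstance(fire, pd.Series):
        return int(fire.ignition_date)
    return int(fire["ignition_date"])
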