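"""Descriptive fire-regime summaries.

Aggregates delineated fire events into annual series (counts, burnt
area, medians of each characteristic), per-management-unit summaries,
coarse-grid (default 6 x 6 km) yearly rasters, and the never-burnt
extent.  Two conservation laws are preserved by construction: a fire is
counted once (by its centroid) for counts/medians, while burnt area is
split across cells by pixel membership, so cell sums equal totals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .grids import Grid, Raster

CHARACTERISTICS = ("size_km2", "day_of_year", "tslf_years", "frp_max")


def _median(s: pd.Series) -> float:
    """Median over the non-missing values; NaN (quietly) when none exist."""
    s = s.dropna()
    return float(s.median()) if len(s) else float("nan")


def annual_series(events: pd.DataFrame, study_area_km2: float | None = None) -> pd.DataFrame:
    """Per-year totals and medians of the fire characteristics.

    Missing-valued characteristics (tslf, frp) are excluded from their
    medians.  ``median_size_top_decile`` is the median size of the
    largest ceil(n/10) fires of the year.
    """
    rows = []
    for year, grp in events.groupby("calendar_year"):
        n = len(grp)
        rec = {
            "year": int(year),
            "n_fires": n,
            "area_burnt_km2": float(grp["size_km2"].sum()),
            "median_size_km2": _median(grp["size_km2"]),
            "median_ignition_day": _median(grp["day_of_year"]),
            "median_tslf_years": _median(grp["tslf_years"]),
            "median_frp": _median(grp["frp_max"]),
            "top_decile_share": top_decile_share(grp),
        }
        top = grp.nlargest(math.ceil(n / 10), "size_km2", keep="first")
        rec["median_size_top_decile"] = _median(top["size_km2"])
        if study_area_km2:
            rec["pct_burnt"] = 100.0 * rec["area_burnt_km2"] / study_area_km2
        rows.append(rec)
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def top_decile_share(events: pd.DataFrame) -> float:
    """Share of total burnt area contributed by the largest ceil(n/10) fires."""
    if len(events) == 0:
        raise ValueError("no events")
    k = math.ceil(len(events) / 10)
    ordered = events.sort_values(["size_km2", "event_id"], ascending=[False, True])
    total = ordered["size_km2"].sum()
    if total == 0:
        return float("nan")
    return float(ordered["size_km2"].head(k).sum() / total)


def assign_units(events: pd.DataFrame, units) -> pd.Series:
    """Unit name per event, by centroid point-in-polygon."""
    out = []
    for _, ev in events.iterrows():
        pt = Point(ev["centroid_x"], ev["centroid_y"])
        out.append(next((u.name for u in units if u.polygon.intersects(pt)), "none"))
    return pd.Series(out, index=events.index, name="unit")


def unit_summary(
    events: pd.DataFrame,
    units,
    records: pd.DataFrame,
    grid: Grid,
) -> pd.DataFrame:
    """Per-unit medians and burnt proportions.

    Events are assigned by centroid; burnt pixels by their cell centre.
    ``proportion_burnt`` is the median over years of (burnt pixel area in
    unit) / (unit area); medians are reported both over all fires and
    over the yearly top-decile fires.
    """
    for i, a in enumerate(units):
        for b in units[i + 1 :]:
            inter = a.polygon.intersection(b.polygon)
            if inter.area > 1e-6 * min(a.polygon.area, b.polygon.area):
                raise ValueError(f"unit polygons overlap: {a.name}, {b.name}")
    ev = events.copy()
    ev["unit"] = assign_units(events, units)

    # burnt pixel membership by cell centre
    x, y = grid.centroid(records["row"].to_numpy(), records["col"].to_numpy())
    pix_unit = []
    for xi, yi in zip(x, y):
        pt = Point(xi, yi)
        pix_unit.append(next((u.name for u in units if u.polygon.intersects(pt)), "none"))
    rec = records.copy()
    rec["unit"] = pix_unit
    from . import calendars as cal

    rec["year"] = rec["burn_date"].map(cal.calendar_year)

    rows = []
    for u in units:
        sub = ev[ev["unit"] == u.name]
        area_km2 = u.polygon.area / 1e6
        burnt_by_year = (
            rec[rec["unit"] == u.name].groupby("year").size() * grid.cell_area_km2
        )
        yearly_burnt = burnt_by_year.reindex(sorted(rec["year"].unique()), fill_value=0.0)
        rec_row = {
            "unit": u.name,
            "unit_area_km2": area_km2,
            "n_fires": int(len(sub)),
            "total_burnt_km2": float(yearly_burnt.sum()),
            "median_annual_burnt_km2": float(yearly_burnt.median()) if len(yearly_burnt) else 0.0,
            "proportion_burnt": float(yearly_burnt.median() / area_km2) if len(yearly_burnt) else 0.0,
        }
        for ch in CHARACTERISTICS:
            rec_row[f"median_{ch}"] = _median(sub[ch]) if len(sub) else float("nan")
        if len(sub):
            k = math.ceil(len(sub) / 10)
            rec_row["median_size_top_decile"] = _median(sub.nlargest(k, "size_km2")["size_km2"])
        else:
            rec_row["median_size_top_decile"] = float("nan")
        rows.append(rec_row)
    return pd.DataFrame(rows)


def rasterize_characteristic(
    events: pd.DataFrame,
    records: pd.DataFrame,
    labels: np.ndarray,
    grid: Grid,
    cell_km: float = 6.0,
) -> dict[str, dict[int, Raster]]:
    """Yearly coarse-grid rasters of the fire regime.

    Per coarse cell and year: ``area_burnt`` sums member burnt-pixel
    area (a fire straddling cells is split, so cell sums conserve the
    yearly total); ``n_fires`` counts event centroids; the median rasters
    use events whose centroid falls in the cell.
    """
    factor = int(round(cell_km * 1000.0 / grid.cell_size))
    coarse = grid.coarsen(factor)
    from . import calendars as cal

    rec_year = records["burn_date"].map(cal.calendar_year).to_numpy()
    rec_cr = records["row"].to_numpy() // factor
    rec_cc = records["col"].to_numpy() // factor

    ev = events
    ev_rows, ev_cols = grid.cells_of(ev["centroid_x"].to_numpy(), ev["centroid_y"].to_numpy())
    ev_cr, ev_cc = ev_rows // factor, ev_cols // factor
    years = sorted(set(int(y) for y in ev["calendar_year"])) if len(ev) else []

    out: dict[str, dict[int, Raster]] = {
        k: {} for k in ("area_burnt", "n_fires", "median_size", "median_ignition",
                        "median_tslf", "median_frp")
    }
    char_map = {
        "median_size": "size_km2",
        "median_ignition": "day_of_year",
        "median_tslf": "tslf_years",
        "median_frp": "frp_max",
    }
    for year in years:
        shape = (coarse.nrows, coarse.ncols)
        area = np.zeros(shape)
        sel = rec_year == year
        np.add.at(area, (rec_cr[sel], rec_cc[sel]), grid.cell_area_km2)
        out["area_burnt"][year] = Raster(coarse, area, name="area_burnt", time=year)

        nf = np.zeros(shape)
        esel = (ev["calendar_year"] == year).to_numpy()
        np.add.at(nf, (ev_cr[esel], ev_cc[esel]), 1.0)
        out["n_fires"][year] = Raster(coarse, nf, name="n_fires", time=year)

        for nm, col in char_map.items():
            med = np.full(shape, np.nan)
            sub = ev[esel]
            if len(sub):
                key = pd.DataFrame({"r": ev_cr[esel], "c": ev_cc[esel], "v": sub[col].to_numpy()})
                for (r, c), g in key.groupby(["r", "c"]):
                    med[int(r), int(c)] = _median(g["v"])
            out[nm][year] = Raster(coarse, med, name=nm, time=year)
    return out


def unburnt_extent(records: pd.DataFrame, grid: Grid, study_mask: np.ndarray | None = None):
    """Area (km^2) and fraction of the study region never burned.

    ``study_mask`` is a boolean raster of in-study cells (default: the
    whole grid).
    """
    mask = np.ones((grid.nrows, grid.ncols), bool) if study_mask is None else study_mask.astype(bool)
    burned = np.zeros_like(mask)
    if len(records):
        burned[records["row"].to_numpy(), records["col"].to_numpy()] = True
    never = mask & ~burned
    area = float(never.sum()) * grid.cell_area_km2
    frac = float(never.sum()) / float(mask.sum())
    return area, frac
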