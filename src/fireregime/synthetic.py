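"""Synthetic savannah landscape generator.

Every input the fire-regime pipeline consumes — burn-date rasters, active
fire detections with radiative power, monthly rainfall surfaces,
management-unit polygons, boma (livestock enclosure) counts in image
footprints and GPS trajectories of migratory grazers — can be generated
here with known ground-truth parameters, so each downstream stage is
testable without any remote-sensing downloads.

Design of the burn generator: each synthetic fire is grown by stochastic
dilation from a seed pixel, with per-pixel burn date equal to the seed
date plus the hop count (capped at 5 days).  Fires ignited in the same
year are kept spatially non-adjacent (one-pixel halo), and the fire
season window keeps repeat burns of a pixel in different years far more
than 5 days apart, so the spatio-temporal flood-fill contract recovers
the true fire labels exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import calendars as cal
from .grids import Grid, Raster

FIRE_SEASON = (150, 270)  # day-of-year window in which synthetic fires ignite

_POLICIES = ("suppress", "active_burn", "communal")


@dataclass(frozen=True)
class ManagementUnit:
    """One management unit: a named polygon with a fire/livestock policy."""

    name: str
    polygon: Polygon
    livestock_permitted: bool = False
    fire_policy: str = "active_burn"

    def __post_init__(self):
        if self.fire_policy not in _POLICIES:
            raise ValueError(f"unknown fire_policy {self.fire_policy!r}")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"unit {self.name!r} has an invalid polygon")


@dataclass
class LandscapeConfig:
    grid_nrows: int = 50
    grid_ncols: int = 50
    pixel_size_m: float = 500.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    years: tuple[int, int] = (2001, 2014)
    seed: int = 0
    units: list[ManagementUnit] = field(default_factory=list)

    def __post_init__(self):
        if self.grid_nrows <= 0 or self.grid_ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")
        if not self.units:
            self.units = default_units(self.grid())
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            raise ValueError("unit names must be unique")

    def grid(self) -> Grid:
        return Grid(
            nrows=self.grid_nrows,
            ncols=self.grid_ncols,
            cell_size=self.pixel_size_m,
            x0=self.origin_xy[0],
            y0=self.origin_xy[1],
        )

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for parameter-recovery tests."""

    fire_labels: np.ndarray | None = None  # event id per burn record
    fires: pd.DataFrame | None = None      # one row per true fire
    boma_slope: float | Callable | None = None
    rainfall_gradient: float | None = None
    rainfall_trend: float | None = None
    bbmm_sigma2: float | None = None
    frp_lognormal: tuple[float, float] | None = None


def default_units(grid: Grid, buffer_cells: int = 4) -> list[ManagementUnit]:
    """A 2x4 tiling of protected rectangles surrounded by a buffer ring.

    Mirrors a multi-unit protected-area complex: most interior units
    exclude livestock and burn actively, two communal units and the
    buffer permit livestock.
    """
    xmin, ymin, xmax, ymax = grid.extent
    buffer_cells = min(buffer_cells, (min(grid.nrows, grid.ncols) - 2) // 2)
    if buffer_cells < 1:
        # grid too small for a ring: a single protected unit
        return [ManagementUnit("unit_1", box(xmin, ymin, xmax, ymax))]
    b = buffer_cells * grid.cell_size
    ixmin, iymin, ixmax, iymax = xmin + b, ymin + b, xmax - b, ymax - b
    units = []
    dx, dy = (ixmax - ixmin) / 4, (iymax - iymin) / 2
    policies = ["active_burn", "active_burn", "suppress", "communal",
                "active_burn", "active_burn", "communal", "suppress"]
    k = 0
    for j in range(2):
        for i in range(4):
            poly = box(ixmin + i * dx, iymin + j * dy, ixmin + (i + 1) * dx, iymin + (j + 1) * dy)
            units.append(
                ManagementUnit(
                    name=f"unit_{k + 1}",
                    polygon=poly,
                    livestock_permitted=policies[k] == "communal",
                    fire_policy=policies[k],
                )
            )
            k += 1
    ring = box(xmin, ymin, xmax, ymax).difference(box(ixmin, iymin, ixmax, iymax))
    units.append(ManagementUnit("buffer", ring, livestock_permitted=True, fire_policy="communal"))
    return units


def _neighbours(row, col, nrows, ncols):
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            r, c = row + dr, col + dc
            if 0 <= r < nrows and 0 <= c < ncols:
                yield r, c


def generate_burn_history(
    cfg: LandscapeConfig,
    n_fires_per_year: int,
    mean_fire_pixels: int,
    size_sigma: float = 0.0,
    n_fires_poisson: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-pixel burn dates for every study year.

    Returns a burn-record table (``row``, ``col``, ``burn_date``) and the
    ground truth labelling each record with its true fire id.  Fire sizes
    are ``mean_fire_pixels`` exactly when ``size_sigma`` is 0, otherwise
    drawn from a truncated log-normal with that log-scale spread around
    the requested mean.  With ``n_fires_poisson`` the yearly fire count
    is a Poisson draw around ``n_fires_per_year`` (real fire numbers
    vary between years); otherwise it is exact.
    """
    if n_fires_per_year < 0:
        raise ValueError("n_fires_per_year must be >= 0")
    if mean_fire_pixels < 1:
        raise ValueError("mean_fire_pixels must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    nrows, ncols = cfg.grid_nrows, cfg.grid_ncols
    capacity = nrows * ncols
    if n_fires_per_year * (mean_fire_pixels + 8) > capacity:
        raise ValueError(
            f"cannot place {n_fires_per_year} fires of ~{mean_fire_pixels} pixels "
            f"(plus separation halos) on a {nrows}x{ncols} grid"
        )

    rows, cols, dates, labels = [], [], [], []
    fire_meta = []
    fire_id = 0
    for year in cfg.year_list():
        occupied = np.zeros((nrows, ncols), dtype=bool)  # burned or halo, this year
        year_day0 = cal.to_day(year, 1, 1)
        n_this_year = (
            int(rng.poisson(n_fires_per_year)) if n_fires_poisson else n_fires_per_year
        )
        for _ in range(n_this_year):
            if size_sigma > 0:
                mu = np.log(mean_fire_pixels) - size_sigma**2 / 2
                target = int(np.clip(round(rng.lognormal(mu, size_sigma)), 1, capacity // 4))
            else:
                target = mean_fire_pixels
            seed_doy = int(rng.integers(FIRE_SEASON[0], FIRE_SEASON[1]))
            seed_date = year_day0 + seed_doy
            patch = None
            for _attempt in range(500):
                r0 = int(rng.integers(0, nrows))
                c0 = int(rng.integers(0, ncols))
                if occupied[r0, c0]:
                    continue
                patch = _grow_patch(r0, c0, target, occupied, rng, nrows, ncols)
                if len(patch) == target:
                    break
                patch = None
            if patch is None:
                raise ValueError(
                    f"could not place fire {fire_id} in year {year}: grid capacity exhausted"
                )
            for (r, c), hops in patch.items():
                rows.append(r)
                cols.append(c)
                dates.append(seed_date + min(hops, 5))
                labels.append(fire_id)
                occupied[r, c] = True
                for rr, cc in _neighbours(r, c, nrows, ncols):
                    occupied[rr, cc] = True
            fire_meta.append(
                {"fire_id": fire_id, "year": year, "ignition_date": seed_date,
                 "size_pixels": len(patch)}
            )
            fire_id += 1

    records = pd.DataFrame({"row": rows, "col": cols, "burn_date": dates}).astype(int)
    truth = SyntheticTruth(
        fire_labels=np.asarray(labels, dtype=int),
        fires=pd.DataFrame(fire_meta, columns=["fire_id", "year", "ignition_date", "size_pixels"]),
    )
    return records, truth


def _grow_patch(r0, c0, target, occupied, rng, nrows, ncols):
    """Stochastic dilation from a seed; returns {(row, col): hop_count}."""
    patch = {(r0, c0): 0}
    frontier = [(r0, c0)]
    while len(patch) < target and frontier:
        idx = int(rng.integers(0, len(frontier)))
        r, c = frontier[idx]
        cands = [
            (rr, cc)
            for rr, cc in _neighbours(r, c, nrows, ncols)
            if (rr, cc) not in patch and not occupied[rr, cc]
        ]
        if not cands:
            frontier.pop(idx)
            continue
        rr, cc = cands[int(rng.integers(0, len(cands)))]
        patch[(rr, cc)] = patch[(r, c)] + 1
        frontier.append((rr, cc))
    return patch


def generate_active_fires(
    records: pd.DataFrame,
    truth: SyntheticTruth,
    grid: Grid,
    detection_prob: float = 0.21,
    frp_scale: float = 10.0,
    frp_log_sd: float = 0.8,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate active-fire point detections with radiative power.

    Each true fire is independently observed with probability
    ``detection_prob`` (emulating overpass timing and small-fire
    omission).  A detected fire contributes one detection at a random
    member pixel, dated within the fire's date span, with fire radiative
    power drawn log-normally: ``log FRP ~ N(log frp_scale, frp_log_sd)``
    in MW/km^2.
    """
    if not 0 <= detection_prob <= 1:
        raise ValueError("detection_prob must be in [0, 1]")
    rng = np.random.default_rng(0) if rng is None else rng
    out = {"x": [], "y": [], "date": [], "frp": []}
    if truth.fire_labels is None or len(records) == 0:
        return pd.DataFrame(out)
    labels = np.asarray(truth.fire_labels)
    for fid in np.unique(labels):
        if rng.random() >= detection_prob:
            continue
        members = records.iloc[np.flatnonzero(labels == fid)]
        pick = members.iloc[int(rng.integers(0, len(members)))]
        x, y = grid.centroid(pick["row"], pick["col"])
        out["x"].append(float(x))
        out["y"].append(float(y))
        out["date"].append(int(pick["burn_date"]))
        out["frp"].append(float(rng.lognormal(np.log(frp_scale), frp_log_sd)))
    df = pd.DataFrame(out)
    truth.frp_lognormal = (float(np.log(frp_scale)), float(frp_log_sd))
    return df


# Relative monthly weights of a bimodal rainfall climatology: short rains
# peak in November, long rains peak in April, dry June-September.
SEASON_WEIGHTS = np.array([0.9, 0.8, 1.4, 1.9, 1.5, 0.4, 0.2, 0.2, 0.4, 0.9, 1.8, 1.6])
SEASON_WEIGHTS = SEASON_WEIGHTS / SEASON_WEIGHTS.sum()


class RainfallSeries:
    """Monthly rainfall surfaces on a (possibly coarse) grid.

    ``data`` has shape (n_months, nrows, ncols); month 0 is ``start``
    (a (year, month) pair) and months are consecutive.
    """

    def __init__(self, grid: Grid, data: np.ndarray, start: tuple[int, int]):
        self.grid = grid
        self.data = np.asarray(data, dtype=float)
        self.start = (int(start[0]), int(start[1]))
        if self.data.ndim != 3 or self.data.shape[1:] != (grid.nrows, grid.ncols):
            raise ValueError("data must be (n_months, nrows, ncols)")
        if np.any(self.data < 0):
            raise ValueError("rainfall must be non-negative")

    @property
    def n_months(self) -> int:
        return self.data.shape[0]

    def index_of(self, year: int, month: int) -> int:
        idx = cal.month_index(year, month, self.start)
        if not 0 <= idx < self.n_months:
            raise ValueError(f"({year}, {month}) outside rainfall series")
        return idx

    def surface(self, year: int, month: int) -> np.ndarray:
        return self.data[self.index_of(year, month)]

    def value(self, year: int, month: int, x: float, y: float) -> float:
        row, col = self.grid.cell_of(x, y)
        return float(self.surface(year, month)[row, col])

    def years(self) -> list[int]:
        y0, m0 = self.start
        y1 = y0 + (m0 - 1 + self.n_months - 1) // 12
        return list(range(y0, y1 + 1))

    def complete_years(self) -> list[int]:
        """Calendar years for which all 12 months are present."""
        return [
            y for y in self.years()
            if cal.month_index(y, 1, self.start) >= 0
            and cal.month_index(y, 12, self.start) < self.n_months
        ]

    def annual_total(self, year: int) -> np.ndarray:
        i0 = self.index_of(year, 1)
        i1 = self.index_of(year, 12)
        return self.data[i0 : i1 + 1].sum(axis=0)


def generate_rainfall(
    cfg: LandscapeConfig,
    west_east_gradient: float = -4.0,
    trend: float = 0.0,
    base_annual: float = 900.0,
    noise_sd: float = 0.05,
    coarsen: int = 10,
    rng: np.random.Generator | None = None,
) -> RainfallSeries:
    """Monthly rainfall with bimodal seasonality and an east-west gradient.

    ``west_east_gradient`` is in mm/yr of annual rainfall per km of
    easting (negative: wetter in the west); ``trend`` is a linear change
    in annual rainfall per year (mm/yr per year).  Multiplicative
    log-normal noise with log-sd ``noise_sd`` perturbs each month.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    rain_grid = cfg.grid().coarsen(coarsen)
    rr, cc = np.meshgrid(np.arange(rain_grid.nrows), np.arange(rain_grid.ncols), indexing="ij")
    x_km = (rain_grid.x0 + (cc + 0.5) * rain_grid.cell_size) / 1000.0
    y0, y1 = cfg.years
    start = (y0, 1)
    frames = []
    for year in range(y0, y1 + 1):
        annual = np.maximum(base_annual + west_east_gradient * x_km + trend * (year - y0), 0.0)
        for month in range(1, 13):
            noise = rng.lognormal(-noise_sd**2 / 2, noise_sd, size=annual.shape)
            frames.append(annual * SEASON_WEIGHTS[month - 1] * noise)
    return RainfallSeries(rain_grid, np.stack(frames), start)


@dataclass
class BomaFootprint:
    footprint_id: int
    polygon: Polygon

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def generate_boma_observations(
    cfg: LandscapeConfig,
    slope: float | Callable[[float, float], float] = 0.05,
    footprint_count: int = 100,
    base_density: float = 2.0,
    obs_years_range: tuple[int, int] = (2, 4),
    buffer_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[BomaFootprint], SyntheticTruth]:
    """Boma counts inside overlapping-image footprints across years.

    Counts are Poisson draws around ``density(year) * footprint_area``,
    with ``density(year) = max(0, base + slope * (year - first_year))``
    evaluated at the footprint centroid; ``slope`` (bomas km^-2 yr^-1)
    and ``base_density`` (bomas km^-2) may each be a scalar or a
    callable of (x, y).  A ``buffer_fraction``
    share of footprints is placed with its centroid in the buffer unit,
    mirroring the concentration of imagery coverage along settlement
    edges, and guaranteeing both interpolation strata have data.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    grid = cfg.grid()
    xmin, ymin, xmax, ymax = grid.extent
    y0 = cfg.years[0]
    years = cfg.year_list()
    lo, hi = obs_years_range
    if hi < 2:
        raise ValueError("some footprints need >= 2 observation years")
    slope_fn = slope if callable(slope) else (lambda x, y: slope)
    base_fn = base_density if callable(base_density) else (lambda x, y: base_density)
    buffer_polys = [u.polygon for u in cfg.units if u.name == "buffer"]

    footprints, rows = [], []
    for fid in range(footprint_count):
        want_buffer = bool(buffer_polys) and fid < buffer_fraction * footprint_count
        # buffer-zone footprints are kept small enough to fit inside the ring
        side = rng.uniform(1000.0, 2000.0) if want_buffer else rng.uniform(2000.0, 6000.0)
        for _ in range(200):
            cx = rng.uniform(xmin + side / 2, xmax - side / 2)
            cy = rng.uniform(ymin + side / 2, ymax - side / 2)
            from shapely.geometry import Point as _Point

            in_buffer = any(p.intersects(_Point(cx, cy)) for p in buffer_polys)
            if in_buffer == want_buffer:
                break
        poly = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        fp = BomaFootprint(fid, poly)
        if fp.area_km2 <= 0:
            raise ValueError("footprint with zero area")
        footprints.append(fp)
        n_obs = int(rng.integers(lo, hi + 1))
        obs_years = sorted(rng.choice(years, size=min(n_obs, len(years)), replace=False))
        for year in obs_years:
            dens = max(0.0, base_fn(cx, cy) + slope_fn(cx, cy) * (year - y0))
            count = int(rng.poisson(dens * fp.area_km2))
            rows.append(
                {"footprint_id": fid, "year": int(year), "count": count,
                 "area_km2": fp.area_km2, "x": cx, "y": cy}
            )
    obs = pd.DataFrame(rows)
    truth = SyntheticTruth(boma_slope=slope)
    return obs, footprints, truth


def generate_trajectories(
    n_individuals: int = 5,
    fix_interval_hours: float = 3.0,
    sigma2: float = 50.0,
    months: Sequence[tuple[int, int]] = ((2010, 7), (2010, 8), (2010, 9)),
    fixes_per_month: Sequence[int] | None = None,
    location_error_sd: float = 20.0,
    start_xy: tuple[float, float] = (12500.0, 12500.0),
    bounds: tuple[float, float, float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Brownian-motion GPS trajectories with known motion variance.

    ``sigma2`` is the Brownian motion variance in m^2/s; the default of
    50 m^2/s gives a daily displacement SD of ~2 km, the order observed
    for migratory grazers.  Per-month fix counts may be unbalanced
    (``fixes_per_month``) to exercise the Voronoi-fracture reweighting
    rule downstream.  ``bounds`` (xmin, ymin, xmax, ymax), if given,
    reflects the walk at the domain edges so paths stay on the study
    grid.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    dt = fix_interval_hours * 3600.0
    rows = []
    for ind in range(n_individuals):
        x, y = start_xy
        t = 0.0
        for mi, (year, month) in enumerate(months):
            n_fix = fixes_per_month[mi] if fixes_per_month is not None else 100
            for _ in range(n_fix):
                step_sd = np.sqrt(sigma2 * dt)
                x += rng.normal(0.0, step_sd)
                y += rng.normal(0.0, step_sd)
                if bounds is not None:
                    # keep a margin so observed fixes (true + GPS error)
                    # stay strictly inside the domain
                    m = 5 * location_error_sd + 1.0
                    x = _reflect(x, bounds[0] + m, bounds[2] - m)
                    y = _reflect(y, bounds[1] + m, bounds[3] - m)
                rows.append(
                    {
                        "individual_id": ind,
                        "t": t,
                        "year": year,
                        "month": month,
                        "x": _clamp(x + rng.normal(0.0, location_error_sd), bounds, 0),
                        "y": _clamp(y + rng.normal(0.0, location_error_sd), bounds, 1),
                    }
                )
                t += dt
    traj = pd.DataFrame(rows)
    return traj, SyntheticTruth(bbmm_sigma2=sigma2)


def _clamp(v: float, bounds, axis: int) -> float:
    if bounds is None:
        return v
    lo, hi = bounds[axis], bounds[axis + 2]
    return min(max(v, lo), hi - 1e-6)


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    while v < lo or v > hi:
        if v < lo:
            v = 2 * lo - v
        if v > hi:
            v = 2 * hi - v
    return v
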