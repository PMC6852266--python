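"""Brownian bridge movement models and population utilization surfaces.

A Brownian bridge movement model (BBMM) treats the path between two
consecutive GPS fixes as Brownian motion conditioned on its endpoints.
At fractional time ``a`` through a gap of duration ``T`` the animal's
position is Gaussian around the linear interpolation of the endpoints
with variance

    s^2(a) = T * sigma2 * a * (1 - a) + ((1 - a)^2 + a^2) * delta^2,

where ``sigma2`` is the Brownian motion variance (m^2/s) and ``delta``
the GPS location-error SD.  Faster transits (short ``T``) therefore
produce narrower corridors.  ``sigma2`` is estimated by the standard
leave-one-out construction: maximise the likelihood of the odd-indexed
fixes under bridges spanning their even-indexed neighbours.

Individual monthly UDs are rasterized at 500 m by time-weighted
quadrature over each bridge, reweighted across months by Voronoi
fractures (inverse monthly fix counts, so the sparsest month gets
weight 1), summed into a monthly population UD, rescaled to 1.0, and
the lowest-utilization tail holding 5% of mass is excluded and the
remainder renormalized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .grids import Grid, Raster

DEFAULT_LOCATION_ERROR_SD = 20.0
QUAD_POINTS = 50
SIGMA2_BOUNDS = (1e-8, 1e4)


def _bridge_terms(fixes: pd.DataFrame):
    t = fixes["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    xy = fixes[["x", "y"]].to_numpy(float)
    return t, xy


def estimate_motion_variance(
    fixes: pd.DataFrame,
    location_error_sd: float = DEFAULT_LOCATION_ERROR_SD,
) -> float:
    """Leave-one-out maximum-likelihood Brownian motion variance (m^2/s)."""
    if len(fixes) < 3:
        raise ValueError("need >= 3 fixes")
    t, xy = _bridge_terms(fixes)
    d2 = location_error_sd**2

    i = np.arange(1, len(t) - 1, 2)
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    a = (t1 - t0) / (t2 - t0)
    mu = xy[i - 1] + a[:, None] * (xy[i + 1] - xy[i - 1])
    dev2 = ((xy[i] - mu) ** 2).sum(axis=1)
    T = t2 - t0

    def nll(log_s2):
        s2 = np.exp(log_s2)
        var = T * s2 * a * (1 - a) + ((1 - a) ** 2 + a**2) * d2
        return float(np.sum(np.log(var) + dev2 / (2 * var)))

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(SIGMA2_BOUNDS[0]), np.log(SIGMA2_BOUNDS[1])), method="bounded"
    )
    s2 = float(np.exp(res.x))
    if s2 <= SIGMA2_BOUNDS[0] * 1.01:
        import warnings

        warnings.warn("motion variance at lower search bound (stationary trajectory?)")
    return s2


def bbmm_ud(
    fixes: pd.DataFrame,
    sigma2: float,
    grid: Grid,
    location_error_sd: float = DEFAULT_LOCATION_ERROR_SD,
    quad_points: int = QUAD_POINTS,
) -> Raster:
    """Rasterized Brownian-bridge utilization distribution, summing to 1.

    The time integral over each bridge is evaluated by midpoint
    quadrature (``quad_points`` per segment); each node contributes an
    isotropic Gaussian whose mass is integrated exactly over each grid
    cell (separable product of normal-CDF differences, truncated at
    5 SD).  Segments are weighted by their duration.
    """
    from scipy.special import ndtr
    t, xy = _bridge_terms(fixes)
    for x, y in xy:
        if not grid.contains(x, y):
            raise ValueError("fix outside grid")
    ud = np.zeros((grid.nrows, grid.ncols))
    cs = grid.cell_size
    # cell edges, for exact Gaussian cell-mass integration
    xe = grid.x0 + np.arange(grid.ncols + 1) * cs
    ye = grid.y0 + np.arange(grid.nrows + 1) * cs
    d2 = location_error_sd**2

    if len(t) == 1 or np.allclose(xy, xy[0]):
        # stationary: all mass from the location-error kernel
        segs = [(xy[0], xy[0], 1.0, 1.0)]
        total_T = 1.0
    else:
        segs = [(xy[k], xy[k + 1], t[k + 1] - t[k], None) for k in range(len(t) - 1)]
        total_T = t[-1] - t[0]

    alphas = (np.arange(quad_points) + 0.5) / quad_points
    for seg in segs:
        p0, p1, T = seg[0], seg[1], seg[2]
        w_seg = T / total_T / quad_points
        for a in alphas:
            mu = p0 + a * (p1 - p0)
            var = T * sigma2 * a * (1 - a) + ((1 - a) ** 2 + a**2) * d2
            sd = max(np.sqrt(var), 1e-9)
            # cell index window covering +/- 5 SD around the node mean
            lo_x = max(int((mu[0] - 5 * sd - grid.x0) // cs), 0)
            hi_x = min(int((mu[0] + 5 * sd - grid.x0) // cs) + 1, grid.ncols)
            lo_y = max(int((mu[1] - 5 * sd - grid.y0) // cs), 0)
            hi_y = min(int((mu[1] + 5 * sd - grid.y0) // cs) + 1, grid.nrows)
            cx = ndtr((xe[lo_x : hi_x + 1] - mu[0]) / sd)
            cy = ndtr((ye[lo_y : hi_y + 1] - mu[1]) / sd)
            gx = np.diff(cx)
            gy = np.diff(cy)
            kern = gy[:, None] * gx[None, :]
            s = kern.sum()
            if s > 0:
                ud[lo_y:hi_y, lo_x:hi_x] += w_seg * kern / s
    ud /= ud.sum()
    return Raster(grid, ud, name="utilization")


def monthly_fix_counts(traj: pd.DataFrame, pooled: bool = True) -> pd.Series:
    """Fix counts per (year, month), pooled across individuals by default."""
    if pooled:
        return traj.groupby(["year", "month"]).size()
    return traj.groupby(["individual_id", "year", "month"]).size()


def voronoi_fracture_weights(counts: pd.Series) -> pd.Series:
    """Inverse-fix-count month weights: w_m = min_m' n_m' / n_m.

    Every Voronoi fracture of month m receives the month's weight, so
    data-rich months are down-weighted and the sparsest month keeps
    weight 1.  Months with zero fixes are excluded upstream.
    """
    counts = counts[counts > 0]
    if len(counts) == 0:
        raise ValueError("no months with fixes")
    return counts.min() / counts


def fracture_masses(ud: Raster, fixes: pd.DataFrame) -> np.ndarray:
    """UD mass per Voronoi fracture (cell assigned to its nearest fix).

    The fractures tile the UD support, so the masses sum to the UD total
    exactly.
    """
    fx = fixes[["x", "y"]].to_numpy(float)
    rr, cc = np.meshgrid(np.arange(ud.grid.nrows), np.arange(ud.grid.ncols), indexing="ij")
    gx, gy = ud.grid.centroid(rr.ravel(), cc.ravel())
    d2 = (gx[:, None] - fx[None, :, 0]) ** 2 + (gy[:, None] - fx[None, :, 1]) ** 2
    nearest = d2.argmin(axis=1)
    masses = np.zeros(len(fx))
    np.add.at(masses, nearest, ud.data.ravel())
    return masses


def population_ud(
    individual_uds: list[Raster],
    month_weights: list[float] | None = None,
    exclusion: str = "cumulative_mass",
    exclude_fraction: float = 0.05,
) -> Raster:
    """Combine weighted individual UDs into a monthly population UD.

    Cellwise weighted sum -> rescale to 1.0 -> drop the lowest-value
    cells whose cumulative utilization totals ``exclude_fraction``
    (``exclusion='percentile'`` instead thresholds at that percentile of
    positive cell values) -> renormalize to 1.0, since downstream
    covariates treat the surface as a distribution.
    """
    if not individual_uds:
        raise ValueError("no UDs for this month")
    grid = individual_uds[0].grid
    if month_weights is None:
        month_weights = [1.0] * len(individual_uds)
    total = np.zeros((grid.nrows, grid.ncols))
    for ud, w in zip(individual_uds, month_weights):
        if ud.grid != grid:
            raise ValueError("UDs must share a grid")
        total += w * ud.data
    total /= total.sum()

    if exclusion == "cumulative_mass":
        flat = total.ravel()
        order = np.argsort(flat)
        csum = np.cumsum(flat[order])
        drop = order[csum <= exclude_fraction]
        flat = flat.copy()
        flat[drop] = 0.0
        total = flat.reshape(total.shape)
    elif exclusion == "percentile":
        pos = total[total > 0]
        thresh = np.percentile(pos, 100 * exclude_fraction)
        total = np.where(total >= thresh, total, 0.0)
    else:
        raise ValueError("exclusion must be 'cumulative_mass' or 'percentile'")
    total /= total.sum()
    return Raster(grid, total, name="population_ud")


def monthly_population_uds(
    traj: pd.DataFrame,
    grid: Grid,
    location_error_sd: float = DEFAULT_LOCATION_ERROR_SD,
    exclusion: str = "cumulative_mass",
    pooled_weights: bool = True,
) -> dict[tuple[int, int], Raster]:
    """Full chain: per-individual BBMMs -> reweighting -> population UDs."""
    counts = monthly_fix_counts(traj, pooled=True)
    weights = voronoi_fracture_weights(counts)
    out: dict[tuple[int, int], Raster] = {}
    for (year, month), mgrp in traj.groupby(["year", "month"]):
        uds, ws = [], []
        for _, igrp in mgrp.groupby("individual_id"):
            igrp = igrp.sort_values("t")
            if len(igrp) < 3:
                continue
            s2 = estimate_motion_variance(igrp, location_error_sd)
            uds.append(bbmm_ud(igrp, s2, grid, location_error_sd))
            ws.append(float(weights.loc[(year, month)]))
        if uds:
            out[(int(year), int(month))] = population_ud(uds, ws, exclusion=exclusion)
    return out


def utilization_3mo(
    x: float,
    y: float,
    year: int,
    month: int,
    uds: dict[tuple[int, int], Raster],
) -> float:
    """Cumulative utilization at (x, y) over the fire month and 2 prior.

    Returns NaN when any of the three months lacks a UD (flagged
    missing); a point outside a month's UD support contributes 0.
    """
    total = 0.0
    for back in range(3):
        m = month - back
        yy = year
        if m <= 0:
            m += 12
            yy -= 1
        key = (yy, m)
        if key not in uds:
            return float("nan")
        ud = uds[key]
        total += ud.value_at(x, y) if ud.grid.contains(x, y) else 0.0
    return total
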