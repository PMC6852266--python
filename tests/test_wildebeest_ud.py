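"""Brownian bridge movement models and population utilization surfaces."""

import numpy as np
import pandas as pd
import pytest

from fireregime import synthetic, wildebeest_ud as wud
from fireregime.grids import Grid, Raster


def traj_frame(xs, ys, dt=3 * 3600.0, year=2010, month=7):
    n = len(xs)
    return pd.DataFrame({
        "individual_id": 0, "t": np.arange(n) * dt,
        "year": year, "month": month, "x": xs, "y": ys,
    })


class TestMotionVariance:
    def test_recovery_from_simulated_brownian_motion(self):
        sigma2 = 40.0
        traj, _ = synthetic.generate_trajectories(
            n_individuals=1, sigma2=sigma2, months=[(2010, 7)],
            fixes_per_month=[500], location_error_sd=20.0,
            rng=np.random.default_rng(55))
        est = wud.estimate_motion_variance(traj, location_error_sd=20.0)
        assert est == pytest.approx(sigma2, rel=0.2)

    def test_stationary_animal_hits_lower_bound(self):
        xs = np.full(21, 1000.0) + np.random.default_rng(1).normal(0, 5, 21)
        ys = np.full(21, 1000.0)
        with pytest.warns(UserWarning, match="lower search bound"):
            est = wud.estimate_motion_variance(traj_frame(xs, ys), location_error_sd=5.0)
        assert est <= wud.SIGMA2_BOUNDS[0] * 1.1

    def test_doubling_displacements_quadruples_variance(self):
        rng = np.random.default_rng(19)
        xs = np.cumsum(rng.normal(0, 400, 101))
        ys = np.cumsum(rng.normal(0, 400, 101))
        base = wud.estimate_motion_variance(traj_frame(xs, ys), location_error_sd=10.0)
        # scaling lengths (incl. the location error) by 2 scales variance by 4
        scaled = wud.estimate_motion_variance(traj_frame(2 * xs, 2 * ys),
                                              location_error_sd=20.0)
        assert scaled == pytest.approx(4 * base, rel=0.01)

    def test_too_few_fixes_errors(self):
        with pytest.raises(ValueError):
            wud.estimate_motion_variance(traj_frame([0, 1], [0, 1]))


class TestBbmmUd:
    def _grid(self, n=40, cell=500.0):
        return Grid(nrows=n, ncols=n, cell_size=cell)

    def test_ud_sums_to_one(self):
        grid = self._grid()
        traj = traj_frame([5000, 9000, 12000], [5000, 8000, 15000])
        ud = wud.bbmm_ud(traj, sigma2=30.0, grid=grid)
        assert ud.data.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ud.data >= 0).all()

    def test_coincident_fixes_concentrate_in_one_cell(self):
        grid = self._grid()
        traj = traj_frame([10250.0, 10250.0], [10250.0, 10250.0])
        ud = wud.bbmm_ud(traj, sigma2=30.0, grid=grid, location_error_sd=20.0)
        r, c = grid.cell_of(10250.0, 10250.0)
        assert ud.data[r, c] > 0.99

    def test_two_fix_bridge_symmetric_about_midpoint(self):
        grid = self._grid(41)
        # endpoints symmetric around the grid centre
        cx = 41 * 500 / 2
        traj = traj_frame([cx - 3000, cx + 3000], [cx, cx])
        ud = wud.bbmm_ud(traj, sigma2=25.0, grid=grid)
        flipped = ud.data[:, ::-1]
        np.testing.assert_allclose(ud.data, flipped, atol=1e-6)

    def test_corridor_width_increases_with_sigma2(self):
        grid = self._grid(41)
        cx = 41 * 500 / 2
        traj = traj_frame([cx - 4000, cx + 4000], [cx, cx])
        widths = []
        for s2 in (5.0, 20.0, 80.0):
            ud = wud.bbmm_ud(traj, sigma2=s2, grid=grid)
            ys = grid.y0 + (np.arange(grid.nrows) + 0.5) * grid.cell_size
            marg = ud.data.sum(axis=1)
            mean_y = (marg * ys).sum()
            widths.append(np.sqrt((marg * (ys - mean_y) ** 2).sum()))
        assert widths[0] < widths[1] < widths[2]

    def test_matches_monte_carlo_oracle(self):
        grid = self._grid(30, cell=500.0)
        rng = np.random.default_rng(77)
        pts_x = [4000.0, 7000.0, 9000.0]
        pts_y = [4000.0, 9000.0, 6000.0]
        dt = 3 * 3600.0
        sigma2, derr = 30.0, 20.0
        traj = traj_frame(pts_x, pts_y, dt=dt)
        ud = wud.bbmm_ud(traj, sigma2=sigma2, grid=grid, location_error_sd=derr)
        # Monte-Carlo oracle: sample times uniformly, positions from the
        # conditional bridge Gaussian, bin onto the grid
        n_mc = 400_000
        seg = rng.integers(0, 2, n_mc)
        a = rng.random(n_mc)
        x0 = np.asarray(pts_x)[seg]
        x1 = np.asarray(pts_x)[seg + 1]
        y0 = np.asarray(pts_y)[seg]
        y1 = np.asarray(pts_y)[seg + 1]
        mu_x = x0 + a * (x1 - x0)
        mu_y = y0 + a * (y1 - y0)
        var = dt * sigma2 * a * (1 - a) + ((1 - a) ** 2 + a**2) * derr**2
        sx = mu_x + rng.normal(0, np.sqrt(var))
        sy = mu_y + rng.normal(0, np.sqrt(var))
        hist = np.zeros((30, 30))
        rr = (sy // 500).astype(int)
        cc = (sx // 500).astype(int)
        ok = (rr >= 0) & (rr < 30) & (cc >= 0) & (cc < 30)
        np.add.at(hist, (rr[ok], cc[ok]), 1.0)
        hist /= hist.sum()
        tv = 0.5 * np.abs(ud.data - hist).sum()
        assert tv < 0.02

    def test_fix_outside_grid_errors(self):
        grid = self._grid(10)
        with pytest.raises(ValueError, match="outside"):
            wud.bbmm_ud(traj_frame([100.0, 99999.0], [100.0, 100.0]), 10.0, grid)


class TestVoronoiReweighting:
    def test_documented_weight_rule(self):
        counts = pd.Series({(2010, 7): 100, (2010, 8): 10})
        w = wud.voronoi_fracture_weights(counts)
        assert w[(2010, 7)] == pytest.approx(0.1)
        assert w[(2010, 8)] == pytest.approx(1.0)

    def test_equal_counts_all_ones(self):
        counts = pd.Series({(2010, m): 50 for m in range(1, 13)})
        assert (wud.voronoi_fracture_weights(counts) == 1.0).all()

    def test_fracture_masses_tile_the_ud(self):
        grid = Grid(nrows=30, ncols=30, cell_size=500.0)
        traj = traj_frame([4000, 7000, 9000, 11000], [4000, 9000, 6000, 12000])
        ud = wud.bbmm_ud(traj, sigma2=30.0, grid=grid)
        masses = wud.fracture_masses(ud, traj)
        assert masses.sum() == pytest.approx(ud.data.sum(), abs=1e-12)
        assert (masses > 0).all()


class TestPopulationUd:
    def _ud(self, seed=0):
        grid = Grid(nrows=25, ncols=25, cell_size=500.0)
        rng = np.random.default_rng(seed)
        data = rng.random((25, 25))
        data /= data.sum()
        return Raster(grid, data)

    def test_mass_retained_is_95_percent_before_renormalization(self):
        ud = self._ud()
        pop = wud.population_ud([ud])
        # reconstruct the retained mass before renormalization
        kept = ud.data[pop.data > 0].sum()
        assert kept == pytest.approx(0.95, abs=0.01)
        assert pop.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_identical_individuals_idempotent(self):
        ud = self._ud()
        one = wud.population_ud([ud])
        two = wud.population_ud([ud, ud])
        np.testing.assert_allclose(one.data, two.data, atol=1e-12)

    def test_percentile_mode_also_normalizes(self):
        ud = self._ud(3)
        pop = wud.population_ud([ud], exclusion="percentile")
        assert pop.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_month_errors(self):
        with pytest.raises(ValueError):
            wud.population_ud([])


class TestUtilization3mo:
    def _uds(self):
        grid = Grid(nrows=10, ncols=10, cell_size=500.0)
        return {
            (2010, m): Raster(grid, np.full((10, 10), 0.01)) for m in (5, 6, 7)
        }, grid

    def test_uniform_uds_sum_three_months(self):
        uds, grid = self._uds()
        got = wud.utilization_3mo(2600, 2600, 2010, 7, uds)
        assert got == pytest.approx(0.03)

    def test_missing_month_flagged(self):
        uds, grid = self._uds()
        assert np.isnan(wud.utilization_3mo(2600, 2600, 2010, 8, uds))

    def test_matches_direct_lookup_oracle(self):
        grid = Grid(nrows=10, ncols=10, cell_size=500.0)
        rng = np.random.default_rng(14)
        uds = {(2011, m): Raster(grid, rng.random((10, 10))) for m in (1, 2, 3)}
        x, y = 3210.0, 4321.0
        want = sum(uds[(2011, m)].data[int(y // 500), int(x // 500)] for m in (1, 2, 3))
        assert wud.utilization_3mo(x, y, 2011, 3, uds) == pytest.approx(want)

    def test_year_boundary_months(self):
        grid = Grid(nrows=5, ncols=5, cell_size=500.0)
        uds = {(2010, 12): Raster(grid, np.full((5, 5), 0.04)),
               (2011, 1): Raster(grid, np.full((5, 5), 0.04)),
               (2011, 2): Raster(grid, np.full((5, 5), 0.04))}
        got = wud.utilization_3mo(1000, 1000, 2011, 2, uds)
        assert got == pytest.approx(0.12)
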