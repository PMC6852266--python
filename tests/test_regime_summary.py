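"""Annual, per-unit and coarse-grid fire-regime summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from fireregime import fire_events, regime_summary, synthetic
from fireregime.grids import Grid


def make_events(sizes_km2, year=2005, **extra):
    n = len(sizes_km2)
    base = {
        "event_id": np.arange(n),
        "size_pixels": (np.asarray(sizes_km2) / 0.25).astype(int),
        "size_km2": np.asarray(sizes_km2, float),
        "ignition_date": np.full(n, 2000),
        "calendar_year": np.full(n, year),
        "rainfall_year": np.full(n, year),
        "day_of_year": np.full(n, 180),
        "tslf_years": np.full(n, np.nan),
        "frp_max": np.full(n, np.nan),
        "centroid_x": np.full(n, 100.0),
        "centroid_y": np.full(n, 100.0),
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestAnnualSeries:
    def test_counts_and_area_arithmetic(self):
        ev = make_events([1.0, 1.0, 1.0])  # three 4-pixel fires
        out = regime_summary.annual_series(ev)
        assert out.loc[0, "n_fires"] == 3
        assert out.loc[0, "area_burnt_km2"] == pytest.approx(3.0)

    def test_percentage_of_study_area(self):
        ev = make_events([8211.1])
        out = regime_summary.annual_series(ev, study_area_km2=36305.0)
        assert out.loc[0, "pct_burnt"] == pytest.approx(22.6, abs=0.05)

    def test_missing_characteristics_excluded_from_medians(self):
        ev = make_events([1.0, 2.0, 4.0])
        ev.loc[0, "frp_max"] = 9.0  # single valued fire
        out = regime_summary.annual_series(ev)
        assert out.loc[0, "median_frp"] == 9.0
        assert np.isnan(out.loc[0, "median_tslf_years"])


class TestTopDecileShare:
    def test_ten_equal_fires(self):
        assert regime_summary.top_decile_share(make_events([2.0] * 10)) == pytest.approx(0.1)

    def test_one_dominant_fire(self):
        sizes = [9.0] + [1.0] * 9
        assert regime_summary.top_decile_share(make_events(sizes)) == pytest.approx(0.5)

    def test_matches_sort_and_sum_oracle(self):
        rng = np.random.default_rng(12)
        sizes = rng.lognormal(0, 1, size=500)
        got = regime_summary.top_decile_share(make_events(sizes))
        k = math.ceil(500 / 10)
        want = np.sort(sizes)[::-1][:k].sum() / sizes.sum()
        assert got == pytest.approx(want, rel=1e-12)

    def test_bounds_for_ten_or_more_fires(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            sizes = rng.lognormal(0, rng.uniform(0, 2), size=int(rng.integers(10, 80)))
            share = regime_summary.top_decile_share(make_events(sizes))
            assert 0.1 <= share <= 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            regime_summary.top_decile_share(make_events([]))


class TestUnitSummary:
    def _setup(self, seed=3):
        cfg = synthetic.LandscapeConfig(grid_nrows=40, grid_ncols=40, seed=seed,
                                        years=(2001, 2004))
        records, _ = synthetic.generate_burn_history(cfg, 12, 6)
        events, labels = fire_events.delineate_fires(records, cfg.grid())
        return cfg, records, events

    def test_single_unit_equals_global(self):
        cfg, records, events = self._setup()
        from shapely.geometry import box

        whole = synthetic.ManagementUnit("all", box(*cfg.grid().extent))
        out = regime_summary.unit_summary(events, [whole], records, cfg.grid())
        assert out.loc[0, "n_fires"] == len(events)
        assert out.loc[0, "total_burnt_km2"] == pytest.approx(len(records) * 0.25)

    def test_printed_percentage_identity(self):
        # protected-area share: 8,001 km^2 of 33,232 km^2 -> 24.1%
        assert round(100 * 8001 / 33232, 1) == 24.1

    def test_overlapping_units_rejected(self):
        cfg, records, events = self._setup()
        from shapely.geometry import box

        a = synthetic.ManagementUnit("a", box(0, 0, 10000, 10000))
        b = synthetic.ManagementUnit("b", box(5000, 0, 20000, 20000))
        with pytest.raises(ValueError, match="overlap"):
            regime_summary.unit_summary(events, [a, b], records, cfg.grid())

    def test_unit_totals_partition_global_totals(self):
        cfg, records, events = self._setup()
        out = regime_summary.unit_summary(events, cfg.units, records, cfg.grid())
        assert out["n_fires"].sum() == len(events)
        assert out["total_burnt_km2"].sum() == pytest.approx(len(records) * 0.25)

    def test_two_unit_split_matches_point_in_polygon_oracle(self):
        cfg, records, events = self._setup()
        from shapely.geometry import Point, box

        xmin, ymin, xmax, ymax = cfg.grid().extent
        xmid = (xmin + xmax) / 2
        west = synthetic.ManagementUnit("west", box(xmin, ymin, xmid, ymax))
        east = synthetic.ManagementUnit("east", box(xmid, ymin, xmax, ymax))
        out = regime_summary.unit_summary(events, [west, east], records, cfg.grid())
        want_west = sum(
            1 for _, e in events.iterrows()
            if west.polygon.intersects(Point(e["centroid_x"], e["centroid_y"]))
        )
        assert out.set_index("unit").loc["west", "n_fires"] == want_west


class TestRasterize:
    def test_single_fire_inside_one_cell(self):
        grid = Grid(nrows=24, ncols=24, cell_size=500.0)
        records = pd.DataFrame({"row": [0, 0, 1, 1], "col": [0, 1, 0, 1],
                                "burn_date": [2000] * 4})
        events, labels = fire_events.delineate_fires(records, grid)
        out = regime_summary.rasterize_characteristic(events, records, labels, grid)
        area = out["area_burnt"][2005 if 2005 in out["area_burnt"] else
                                 list(out["area_burnt"])[0]]
        assert area.data[0, 0] == pytest.approx(1.0)
        assert area.data.sum() == pytest.approx(1.0)

    def test_straddling_fire_split_but_conserved(self):
        grid = Grid(nrows=24, ncols=24, cell_size=500.0)
        # a 4-pixel fire crossing the 12-pixel coarse-cell boundary
        records = pd.DataFrame({"row": [0] * 4, "col": [10, 11, 12, 13],
                                "burn_date": [2000] * 4})
        events, labels = fire_events.delineate_fires(records, grid)
        out = regime_summary.rasterize_characteristic(events, records, labels, grid)
        year = list(out["area_burnt"])[0]
        area = out["area_burnt"][year]
        assert area.data[0, 0] == pytest.approx(0.5)
        assert area.data[0, 1] == pytest.approx(0.5)
        assert area.data.sum() == pytest.approx(events["size_km2"].sum())
        # the fire itself is counted once, in its centroid's cell
        assert out["n_fires"][year].data.sum() == 1

    def test_random_events_match_binning_oracle(self):
        cfg = synthetic.LandscapeConfig(grid_nrows=36, grid_ncols=36, seed=5,
                                        years=(2001, 2003))
        records, _ = synthetic.generate_burn_history(cfg, 10, 7)
        events, labels = fire_events.delineate_fires(records, cfg.grid())
        out = regime_summary.rasterize_characteristic(events, records, labels,
                                                      cfg.grid(), cell_km=6.0)
        import fireregime.calendars as cal

        for year, ras in out["area_burnt"].items():
            sel = records["burn_date"].map(cal.calendar_year) == year
            want = np.zeros_like(ras.data)
            for _, r in records[sel].iterrows():
                want[int(r["row"]) // 12, int(r["col"]) // 12] += 0.25
            np.testing.assert_allclose(ras.data, want)
            # conservation: cells sum to the yearly total
            yearly = events.loc[events["calendar_year"] == year, "size_km2"].sum()
            assert ras.data.sum() == pytest.approx(yearly)


class TestUnburntExtent:
    def test_all_burned(self):
        grid = Grid(nrows=4, ncols=4, cell_size=500.0)
        rr, cc = np.meshgrid(range(4), range(4), indexing="ij")
        records = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel(),
                                "burn_date": 100})
        area, frac = regime_summary.unburnt_extent(records, grid)
        assert area == 0.0 and frac == 0.0

    def test_none_burned(self):
        grid = Grid(nrows=4, ncols=4, cell_size=500.0)
        area, frac = regime_summary.unburnt_extent(pd.DataFrame(columns=["row", "col"]), grid)
        assert area == pytest.approx(16 * 0.25)
        assert frac == 1.0

    def test_random_history_complement_oracle(self):
        rng = np.random.default_rng(51)
        grid = Grid(nrows=20, ncols=20, cell_size=500.0)
        rows = rng.integers(0, 20, 150)
        cols = rng.integers(0, 20, 150)
        records = pd.DataFrame({"row": rows, "col": cols,
                                "burn_date": rng.integers(0, 999, 150)})
        area, frac = regime_summary.unburnt_extent(records, grid)
        burned_cells = len(set(zip(rows.tolist(), cols.tolist())))
        assert area == pytest.approx((400 - burned_cells) * 0.25)
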