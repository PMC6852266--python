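"""Shared fixtures: small synthetic landscapes and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fireregime.grids import Grid
from fireregime.synthetic import LandscapeConfig, RainfallSeries


@pytest.fixture
def grid10() -> Grid:
    return Grid(nrows=10, ncols=10, cell_size=500.0)


@pytest.fixture
def land20() -> LandscapeConfig:
    return LandscapeConfig(grid_nrows=20, grid_ncols=20, seed=11, years=(2001, 2005))


def brute_force_partition(records: pd.DataFrame, max_gap_days: int = 5,
                          connectivity: int = 8) -> np.ndarray:
    """All-pairs union-find oracle for the flood-fill clustering.

    Deliberately independent of the package implementation: O(n^2)
    comparison of every record pair, path-compression-free DSU.
    """
    n = len(records)
    rows = records["row"].to_numpy()
    cols = records["col"].to_numpy()
    dates = records["burn_date"].to_numpy()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            dr, dc = abs(rows[i] - rows[j]), abs(cols[i] - cols[j])
            if connectivity == 8:
                adjacent = dr <= 1 and dc <= 1
            else:
                adjacent = dr + dc <= 1
            if adjacent and abs(dates[i] - dates[j]) <= max_gap_days:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Whether two labelings describe the same partition (up to renaming)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))


def random_records(rng: np.random.Generator, n: int, nrows: int, ncols: int,
                   date_range: tuple[int, int] = (2000, 2100)) -> pd.DataFrame:
    """Unique random burn records on a small grid."""
    seen, rows = set(), []
    while len(rows) < n:
        r = int(rng.integers(0, nrows))
        c = int(rng.integers(0, ncols))
        d = int(rng.integers(*date_range))
        if (r, c, d) not in seen:
            seen.add((r, c, d))
            rows.append({"row": r, "col": c, "burn_date": d})
    return pd.DataFrame(rows)


def uniform_rain(grid: Grid, value: float, start=(2001, 1), n_months: int = 48) -> RainfallSeries:
    data = np.full((n_months, grid.nrows, grid.ncols), float(value))
    return RainfallSeries(grid, data, start)
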