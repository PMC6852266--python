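"""Lightweight georeferenced grids and rasters.

A :class:`Grid` is a regular rectangular grid in projected map units
(metres).  Row 0 is the southernmost row; the grid origin ``(x0, y0)`` is
the lower-left corner.  Cell ownership follows the half-open convention
``[x, x + size) x [y, y + size)`` so every point belongs to exactly one
cell and boundary points are never double-assigned.

Rasters are written and read as plain-text ESRI ASCII grids (``.asc``),
which any GIS can ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    nrows: int
    ncols: int
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self):
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point, half-open convention."""
        col = math.floor((x - self.x0) / self.cell_size)
        row = math.floor((y - self.y0) / self.cell_size)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        col = (x - self.x0) / self.cell_size
        row = (y - self.y0) / self.cell_size
        return 0 <= row < self.nrows and 0 <= col < self.ncols

    def centroid(self, row, col):
        """Map coordinates of cell centre(s); accepts scalars or arrays."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cells_of(self, x, y):
        """Vectorized cell lookup; returns (rows, cols) int arrays."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        if np.any((row < 0) | (row >= self.nrows) | (col < 0) | (col >= self.ncols)):
            raise ValueError("point(s) outside grid")
        return row, col

    def coarsen(self, factor: int) -> "Grid":
        """Grid of ``factor x factor`` blocks; final row/col padded if needed."""
        return Grid(
            nrows=-(-self.nrows // factor),
            ncols=-(-self.ncols // factor),
            cell_size=self.cell_size * factor,
            x0=self.x0,
            y0=self.y0,
        )


@dataclass
class Raster:
    """A single-band gridded surface; ``np.nan`` marks nodata."""

    grid: Grid
    data: np.ndarray
    name: str = ""
    time: object = None  # e.g. a year, or a (year, month) pair

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("data shape does not match grid")

    def value_at(self, x: float, y: float) -> float:
        row, col = self.grid.cell_of(x, y)
        return float(self.data[row, col])

    def copy_with(self, data: np.ndarray, **kw) -> "Raster":
        return Raster(grid=self.grid, data=data, **{"name": self.name, "time": self.time, **kw})


def write_ascii_grid(raster: Raster, path) -> None:
    g = raster.grid
    data = np.where(np.isfinite(raster.data), raster.data, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.x0!r}\n")
        fh.write(f"yllcorner {g.y0!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        # ESRI ASCII grids list the northernmost row first
        for row in data[::-1]:
            fh.write(" ".join(repr(v) for v in row) + "\n")


def read_ascii_grid(path, name: str = "", time=None) -> Raster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        rows = [np.array(line.split(), dtype=float) for line in fh if line.strip()]
    data = np.vstack(rows)[::-1]
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    grid = Grid(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x0=header["xllcorner"],
        y0=header["yllcorner"],
    )
    return Raster(grid=grid, data=data, name=name, time=time)
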