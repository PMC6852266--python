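"""Fire-event delineation from per-pixel burn dates.

Individual fires are delineated from a burned-area raster stack by a
spatio-temporal flood fill: two burn records belong to the same fire
event iff they are connected by a chain of spatially adjacent record
pairs whose burn dates differ by at most ``max_gap_days`` (default 5).
The partition is the transitive closure of that relation (union-find
semantics), so an event's total date span may exceed the gap tolerance —
that is what a flood fill computes.

Each event then receives four characteristics:

* size — number of member pixels, and area in km^2;
* ignition date — the earliest burn date among member pixels, carried as
  calendar year, rainfall year and a 0-based day of year (Jan 1 -> 0);
* time since last fire — the mean, over member pixels that burned at
  least once before, of (ignition date - most recent prior burn date) in
  365.25-day years; missing when no member pixel burned before;
* fire radiative power — the maximum radiative power (MW/km^2) among
  active-fire detections falling inside the event footprint within +/- 1
  day of the event's date span; missing when no detection matches, since
  burn scars and thermal anomalies have different detection
  probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calendars as cal
from .grids import Grid

REQUIRED_COLUMNS = ("row", "col", "burn_date")


@dataclass
class FireEvent:
    event_id: int
    pixels: pd.DataFrame  # row, col, burn_date
    centroid_xy: tuple[float, float]
    size_pixels: int
    size_km2: float
    ignition_date: int
    calendar_year: int
    rainfall_year: int
    day_of_year: int
    tslf_years: float  # NaN when no member pixel burned before
    frp_max: float     # NaN when no detection matched


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    dup = records.duplicated(subset=list(REQUIRED_COLUMNS))
    if dup.any():
        first = records.loc[dup.idxmax(), list(REQUIRED_COLUMNS)]
        raise ValueError(
            "duplicate burn record (row={row}, col={col}, burn_date={burn_date})".format(**first)
        )
    return records


def cluster_burned_pixels(
    records: pd.DataFrame,
    max_gap_days: int = 5,
    connectivity: int = 8,
) -> np.ndarray:
    """Partition burn records into fire events by spatio-temporal flood fill.

    Returns an integer label per record.  Labels are assigned
    deterministically: events are numbered 0..k-1 in order of ignition
    date, then row, then column of their first-igniting pixel.
    Records at the same pixel (repeat burns) are merged when their dates
    are within the gap tolerance, otherwise they seed distinct events.
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    _validate_records(records)
    n = len(records)
    if n == 0:
        return np.empty(0, dtype=int)

    rows = records["row"].to_numpy()
    cols = records["col"].to_numpy()
    dates = records["burn_date"].to_numpy()

    by_pixel: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        by_pixel.setdefault((int(rows[i]), int(cols[i])), []).append(i)

    if connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    else:
        offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]

    uf = _UnionFind(n)
    for i in range(n):
        r, c, d = int(rows[i]), int(cols[i]), dates[i]
        for dr, dc in offsets:
            for j in by_pixel.get((r + dr, c + dc), ()):
                if j != i and abs(dates[j] - d) <= max_gap_days:
                    uf.union(i, j)

    roots = np.array([uf.find(i) for i in range(n)])
    # deterministic event ids: order components by (ignition, row, col)
    order_key = {}
    for root in np.unique(roots):
        members = np.flatnonzero(roots == root)
        k = min(members, key=lambda i: (dates[i], rows[i], cols[i]))
        order_key[root] = (dates[k], rows[k], cols[k])
    ordered = sorted(order_key, key=order_key.get)
    remap = {root: new for new, root in enumerate(ordered)}
    return np.array([remap[r] for r in roots], dtype=int)


def burn_dates_by_pixel(records: pd.DataFrame) -> dict[tuple[int, int], np.ndarray]:
    """Map (row, col) -> array of burn dates, for time-since-fire lookups."""
    return {
        key: grp["burn_date"].to_numpy()
        for key, grp in records.groupby(["row", "col"])
    }


def compute_characteristics(
    event_pixels: pd.DataFrame,
    event_id: int,
    grid: Grid,
    prior_records: pd.DataFrame | None = None,
    prior_by_pixel: dict | None = None,
) -> FireEvent:
    """Derive the per-fire characteristics for one delineated event.

    ``prior_records`` is the burn history available for the time-since-
    last-fire computation (or pass a precomputed ``prior_by_pixel`` map
    from :func:`burn_dates_by_pixel` when calling in a loop); records
    belonging to the event itself are ignored automatically — only
    burns strictly before the fire's ignition count.
    """
    if len(event_pixels) == 0:
        raise ValueError("event has no pixels")
    ignition = int(event_pixels["burn_date"].min())
    x, y = grid.centroid(event_pixels["row"].to_numpy(), event_pixels["col"].to_numpy())
    centroid = (float(np.mean(x)), float(np.mean(y)))
    size_pixels = int(len(event_pixels))
    size_km2 = size_pixels * grid.cell_area_km2

    if prior_by_pixel is None and prior_records is not None and len(prior_records):
        prior_by_pixel = burn_dates_by_pixel(prior_records)
    tslf = np.nan
    if prior_by_pixel:
        gaps = []
        for r_, c_ in zip(event_pixels["row"].astype(int), event_pixels["col"].astype(int)):
            prev = prior_by_pixel.get((r_, c_))
            if prev is None:
                continue
            prev = prev[prev < ignition]
            if len(prev):
                gaps.append((ignition - prev.max()) / cal.DAYS_PER_YEAR)
        if gaps:
            tslf = float(np.mean(gaps))

    return FireEvent(
        event_id=event_id,
        pixels=event_pixels.reset_index(drop=True),
        centroid_xy=centroid,
        size_pixels=size_pixels,
        size_km2=size_km2,
        ignition_date=ignition,
        calendar_year=cal.calendar_year(ignition),
        rainfall_year=cal.rainfall_year(ignition),
        day_of_year=cal.day_of_year0(ignition),
        tslf_years=tslf,
        frp_max=np.nan,
    )


def attach_frp(
    event: FireEvent,
    detections: pd.DataFrame,
    grid: Grid,
    date_tolerance_days: int = 1,
) -> FireEvent:
    """Set ``frp_max`` from active-fire detections matching the event.

    A detection matches when its containing 500 m cell is a member pixel
    of the event and its date lies within the event's burn-date span
    widened by ``date_tolerance_days`` on each side (satellite overpass
    timing and burn-scar composite dating are offset by up to a day).
    """
    if detections is None or len(detections) == 0:
        return event
    footprint = set(zip(event.pixels["row"].astype(int), event.pixels["col"].astype(int)))
    dmin = int(event.pixels["burn_date"].min()) - date_tolerance_days
    dmax = int(event.pixels["burn_date"].max()) + date_tolerance_days
    best = np.nan
    for _, det in detections.iterrows():
        if not dmin <= det["date"] <= dmax:
            continue
        if not grid.contains(det["x"], det["y"]):
            continue
        if grid.cell_of(det["x"], det["y"]) in footprint:
            if det["frp"] < 0:
                raise ValueError("negative radiative power in detections")
            if np.isnan(best) or det["frp"] > best:
                best = float(det["frp"])
    event.frp_max = best
    return event


def delineate_fires(
    records: pd.DataFrame,
    grid: Grid,
    detections: pd.DataFrame | None = None,
    max_gap_days: int = 5,
    connectivity: int = 8,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Full delineation: cluster records, compute characteristics, attach FRP.

    Returns (events table, per-record labels).  The events table has one
    row per fire with all four characteristics plus centroid and dates.
    """
    labels = cluster_burned_pixels(records, max_gap_days=max_gap_days, connectivity=connectivity)
    if len(labels) == 0:
        cols = ["event_id", "size_pixels", "size_km2", "ignition_date", "calendar_year",
                "rainfall_year", "day_of_year", "tslf_years", "frp_max", "centroid_x", "centroid_y"]
        return pd.DataFrame(columns=cols), labels

    # pre-bucket detections by containing cell so each event only scans
    # candidates on its own footprint
    det_by_cell: dict[tuple[int, int], list[tuple[int, float]]] = {}
    if detections is not None and len(detections):
        drows, dcols = grid.cells_of(detections["x"].to_numpy(), detections["y"].to_numpy())
        for (r, c, d, f) in zip(drows, dcols, detections["date"], detections["frp"]):
            det_by_cell.setdefault((int(r), int(c)), []).append((int(d), float(f)))

    events = []
    history = burn_dates_by_pixel(records)
    for eid in range(int(labels.max()) + 1):
        member = records.iloc[np.flatnonzero(labels == eid)]
        ev = compute_characteristics(member, eid, grid, prior_by_pixel=history)
        if det_by_cell:
            dmin = int(member["burn_date"].min()) - 1
            dmax = int(member["burn_date"].max()) + 1
            best = np.nan
            for key in zip(member["row"].astype(int), member["col"].astype(int)):
                for d, f in det_by_cell.get(key, ()):
                    if dmin <= d <= dmax and (np.isnan(best) or f > best):
                        best = f
            ev.frp_max = best
        events.append(ev)
    table = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "size_pixels": [e.size_pixels for e in events],
            "size_km2": [e.size_km2 for e in events],
            "ignition_date": [e.ignition_date for e in events],
            "calendar_year": [e.calendar_year for e in events],
            "rainfall_year": [e.rainfall_year for e in events],
            "day_of_year": [e.day_of_year for e in events],
            "tslf_years": [e.tslf_years for e in events],
            "frp_max": [e.frp_max for e in events],
            "centroid_x": [e.centroid_xy[0] for e in events],
            "centroid_y": [e.centroid_xy[1] for e in events],
        }
    )
    return table, labels
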