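"""Calendar arithmetic on integer day numbers.

All burn dates, detection dates and trajectory timestamps in this package
are integers counting days since 2000-01-01 (day 0).  Integer day numbers
make the 5-day fire-merging rule and the rainfall-year bookkeeping exact,
with leap years handled by the standard library.
"""

from __future__ import annotations

import datetime as _dt

EPOCH = _dt.date(2000, 1, 1)
_EPOCH_ORD = EPOCH.toordinal()

DAYS_PER_YEAR = 365.25


def to_day(year: int, month: int, day: int) -> int:
    """Convert a calendar date to an integer day number (2000-01-01 = 0)."""
    return _dt.date(year, month, day).toordinal() - _EPOCH_ORD


def from_day(day: int) -> _dt.date:
    """Inverse of :func:`to_day`."""
    return _dt.date.fromordinal(int(day) + _EPOCH_ORD)


def calendar_year(day: int) -> int:
    return from_day(day).year


def day_of_year0(day: int) -> int:
    """0-based ordinal day of year: Jan 1 -> 0, Dec 31 -> 364 (365 in leap years)."""
    d = from_day(day)
    return d.timetuple().tm_yday - 1


def year_month(day: int) -> tuple[int, int]:
    d = from_day(day)
    return d.year, d.month


def rainfall_year(day: int) -> int:
    """Label of the rainfall year containing ``day``.

    A rainfall year runs October through the following September and is
    labelled by its ending September: Oct 2005 - Sep 2006 -> 2006.
    """
    y, m = year_month(day)
    return y + 1 if m >= 10 else y


def rainfall_year_start(label: int) -> tuple[int, int]:
    """(year, month) of the first month (October) of rainfall year ``label``."""
    return label - 1, 10


def month_range(start: tuple[int, int], end: tuple[int, int]):
    """Yield (year, month) pairs from ``start`` to ``end`` inclusive."""
    y, m = start
    while (y, m) <= tuple(end):
        yield y, m
        m += 1
        if m == 13:
            y, m = y + 1, 1


def month_index(year: int, month: int, start: tuple[int, int]) -> int:
    """0-based index of (year, month) within a monthly series starting at ``start``."""
    return (year - start[0]) * 12 + (month - start[1])
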