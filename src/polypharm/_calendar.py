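"""Day-index arithmetic for a single observation year.

All coverage computations use integer day offsets from 1 January of the
observation year (day 0).  Intervals are half-open ``[start, end)``: a
one-day supply dispensed on day ``d`` covers exactly day ``d``.  Negative
offsets address the look-back year (fills dispensed the year before whose
supply can carry into the observation year).
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

__all__ = [
    "to_day",
    "to_date",
    "year_length",
    "month_bounds",
    "quarter_bounds",
    "year_bounds",
    "window_bounds",
]


def to_day(date: dt.date, observation_year: int) -> int:
    """Offset of *date* from 1 January of *observation_year* (day 0)."""
    return (date - dt.date(observation_year, 1, 1)).days


def to_date(day: int, observation_year: int) -> dt.date:
    return dt.date(observation_year, 1, 1) + dt.timedelta(days=day)


def year_length(observation_year: int) -> int:
    return 366 if _is_leap(observation_year) else 365


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def month_bounds(observation_year: int) -> list[tuple[int, int]]:
    """Half-open ``[start, end)`` day-index bounds of the 12 calendar months."""
    bounds = []
    for m in range(1, 13):
        start = to_day(dt.date(observation_year, m, 1), observation_year)
        if m == 12:
            end = year_length(observation_year)
        else:
            end = to_day(dt.date(observation_year, m + 1, 1), observation_year)
        bounds.append((start, end))
    return bounds


def quarter_bounds(observation_year: int) -> list[tuple[int, int]]:
    """Bounds of the 4 calendar quarters (Q1 = Jan-Mar, ...)."""
    months = month_bounds(observation_year)
    return [(months[3 * q][0], months[3 * q + 2][1]) for q in range(4)]


def year_bounds(observation_year: int) -> list[tuple[int, int]]:
    return [(0, year_length(observation_year))]


def window_bounds(granularity: str, observation_year: int) -> list[tuple[int, int]]:
    """Window bounds for a granularity name (``ANNUAL``/``QUARTER``/``MONTH``)."""
    g = granularity.upper()
    if g == "ANNUAL":
        return year_bounds(observation_year)
    if g == "QUARTER":
        return quarter_bounds(observation_year)
    if g == "MONTH":
        return month_bounds(observation_year)
    raise ValueError(f"unknown granularity: {granularity!r}")
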