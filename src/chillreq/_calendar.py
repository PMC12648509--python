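"""Season-relative day indexing for dormancy analyses.

A dormant season labelled by its bloom year ``y`` starts in the previous
autumn.  Days are indexed relative to the turn of the year: Jan 1 of ``y``
is +1 and days before Jan 1 carry non-positive indices counting down to
the season start (index = DOY - days in the previous year, so Dec 31 is 0
and Nov 1 is -60 regardless of leap years).
"""

from __future__ import annotations

import calendar
import datetime as dt

__all__ = ["day_index", "index_to_date", "season_day_indices", "season_start_index"]


def day_index(date: dt.date, season_year: int) -> int:
    """Season-relative index of ``date`` within the season blooming in ``season_year``."""
    doy = date.timetuple().tm_yday
    if date.year == season_year:
        return doy
    if date.year == season_year - 1:
        return doy - (366 if calendar.isleap(date.year) else 365)
    raise ValueError(f"{date} is not part of season {season_year}")


def index_to_date(index: int, season_year: int) -> dt.date:
    """Calendar date of a season-relative day index (inverse of :func:`day_index`)."""
    if index >= 1:
        return dt.date(season_year, 1, 1) + dt.timedelta(days=index - 1)
    return dt.date(season_year - 1, 12, 31) + dt.timedelta(days=index)


def season_start_index(split_month: int) -> int:
    """Index of the first day of ``split_month`` in the pre-bloom year.

    Months after February give the same index in leap and common years,
    so the grid of indices is shared by every season.
    """
    if not 3 <= split_month <= 12:
        raise ValueError("split_month must be a month after February (3-12)")
    # non-leap arithmetic; identical for leap years for months > 2
    doy = dt.date(2001, split_month, 1).timetuple().tm_yday
    return doy - 365


def season_day_indices(split_month: int, end_day: int) -> list[int]:
    """Ordered day-index grid from the season start through ``end_day`` (a positive DOY)."""
    start = season_start_index(split_month)
    if end_day < 1:
        raise ValueError("end_day must be a positive day of year")
    return list(range(start, end_day + 1))
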