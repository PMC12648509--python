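"""Daily temperature QC, gap-filling and hourly reconstruction.

Chill models operate on hourly temperatures, but orchard weather stations
usually report only daily extremes (Tmax/Tmin).  The standard idealized
day is used to reconstruct the diurnal course: a sine from sunrise to
sunset whose half-period is stretched by 4 h so the maximum falls in the
afternoon, followed by a logarithmic decay through the night towards the
next morning's minimum.  Sunrise/sunset come from latitude and solar
declination (7-term Fourier series in the day angle).

Daily records are quality-checked for calendar gaps and missing extremes,
and gaps are filled by linear interpolation before reconstruction.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "SolarTimes",
    "CoverageError",
    "WEATHER_COLUMNS",
    "read_weather",
    "write_weather",
    "check_temperature_record",
    "fix_weather",
    "trim_to_period",
    "solar_times",
    "make_hourly_temps",
]

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ["Day", "JDay", "Month", "Year", "Tmax", "Tmin"]


class CoverageError(ValueError):
    """The weather record does not cover a required date range."""


@dataclass
class QCReport:
    """Completeness summary of a daily temperature record."""

    n_missing_tmin: int
    n_missing_tmax: int
    n_missing_days: int
    gap_lengths: list[int]
    date_range: tuple[dt.date, dt.date]
    interpolated_days: list[dt.date] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_missing_tmin": self.n_missing_tmin,
            "n_missing_tmax": self.n_missing_tmax,
            "n_missing_days": self.n_missing_days,
            "gap_lengths": self.gap_lengths,
            "date_range": [self.date_range[0].isoformat(), self.date_range[1].isoformat()],
            "interpolated_days": [d.isoformat() for d in self.interpolated_days],
            "flags": self.flags,
        }


@dataclass(frozen=True)
class SolarTimes:
    sunrise: float  # hour of day, decimal
    sunset: float
    daylength: float  # hours


def read_weather(source: str | Path | pd.DataFrame, sheet: str | int = 0) -> pd.DataFrame:
    """Read a daily weather table with columns Day, JDay, Month, Year, Tmax, Tmin."""
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xls"):
            raw = pd.read_excel(path, sheet_name=sheet)
        else:
            raw = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in raw.columns]
    if missing:
        raise CoverageError(f"weather table lacks required column(s): {missing}")
    out = raw[WEATHER_COLUMNS].copy()
    for col in ("Day", "JDay", "Month", "Year"):
        out[col] = out[col].astype(int)
    for col in ("Tmax", "Tmin"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out = out.sort_values(["Year", "Month", "Day"]).reset_index(drop=True)
    return out


def write_weather(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False)


def _dates(table: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(dict(year=table["Year"], month=table["Month"], day=table["Day"]))


def check_temperature_record(table: pd.DataFrame) -> QCReport:
    """Report missing calendar days and missing Tmin/Tmax values (read-only)."""
    dates = _dates(table)
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    present = pd.DatetimeIndex(dates)
    n_missing_days = len(full) - len(present.unique())
    merged = table.set_index(present).reindex(full)
    missing_mask = merged["Tmin"].isna() | merged["Tmax"].isna()
    gap_lengths = []
    run = 0
    for miss in missing_mask:
        if miss:
            run += 1
        elif run:
            gap_lengths.append(run)
            run = 0
    if run:
        gap_lengths.append(run)
    return QCReport(
        n_missing_tmin=int(merged["Tmin"].isna().sum()),
        n_missing_tmax=int(merged["Tmax"].isna().sum()),
        n_missing_days=n_missing_days,
        gap_lengths=gap_lengths,
        date_range=(dates.min().date(), dates.max().date()),
    )


def fix_weather(table: pd.DataFrame, max_gap: int = 30) -> tuple[pd.DataFrame, QCReport]:
    """Fill missing days/values by linear interpolation between valid neighbours.

    Boundary gaps (no neighbour on one side) are filled with the nearest
    valid value.  Gaps longer than ``max_gap`` days are still filled but
    flagged prominently in the report.
    """
    report = check_temperature_record(table)
    dates = _dates(table)
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    out = table.set_index(pd.DatetimeIndex(dates)).reindex(full)
    interpolated = []
    for col in ("Tmin", "Tmax"):
        missing = out[col].isna()
        if missing.any():
            out[col] = out[col].interpolate(method="linear", limit_direction="both")
            interpolated.extend(full[missing])
    # rebuild calendar columns for any inserted days
    out["Year"] = out.index.year.astype("int64")
    out["Month"] = out.index.month.astype("int64")
    out["Day"] = out.index.day.astype("int64")
    out["JDay"] = out.index.dayofyear.astype("int64")
    report.interpolated_days = sorted({d.date() for d in interpolated})
    long_gaps = [g for g in report.gap_lengths if g > max_gap]
    for g in long_gaps:
        flag = f"gap of {g} consecutive missing days exceeds max_gap={max_gap}; filled by interpolation"
        report.flags.append(flag)
        logger.warning("fix_weather: %s", flag)
    if report.n_missing_tmin or report.n_missing_tmax or report.n_missing_days:
        logger.info(
            "fix_weather: interpolated %d day(s) (%d missing Tmin, %d missing Tmax, %d missing days)",
            len(report.interpolated_days),
            report.n_missing_tmin,
            report.n_missing_tmax,
            report.n_missing_days,
        )
    return out.reset_index(drop=True)[WEATHER_COLUMNS], report


def trim_to_period(table: pd.DataFrame, bloom_records) -> pd.DataFrame:
    """Keep weather from Jan 1 of the year before the earliest bloom season."""
    if table.empty or not bloom_records:
        raise ValueError("trim_to_period requires non-empty weather and bloom records")
    start_year = min(r.year for r in bloom_records) - 1
    start = pd.Timestamp(start_year, 1, 1)
    dates = _dates(table)
    if dates.min() > start:
        raise CoverageError(
            f"weather record starts {dates.min().date()} but must cover from {start.date()} "
            f"(one year before the earliest bloom season)"
        )
    return table.loc[dates >= start].reset_index(drop=True)


def solar_times(jday: int, latitude: float) -> SolarTimes:
    """Sunrise, sunset and daylength (hours) from day of year and latitude.

    Uses the day-angle Fourier series for solar declination; the hour angle
    cosine is clipped to [-1, 1] so polar day/night degrade gracefully to
    24/0 h daylength.
    """
    if not -90 <= latitude <= 90:
        raise ValueError("latitude must be within [-90, 90] degrees")
    gamma = 2 * math.pi * (jday - 1) / 365.0
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    lat = math.radians(latitude)
    cos_h0 = -math.tan(lat) * math.tan(decl)
    cos_h0 = min(1.0, max(-1.0, cos_h0))
    h0 = math.acos(cos_h0)
    daylength = 24.0 * h0 / math.pi
    return SolarTimes(sunrise=12.0 - daylength / 2, sunset=12.0 + daylength / 2, daylength=daylength)


def _day_curve(h: float, tmin: float, tmax: float, sun: SolarTimes) -> float:
    """Daytime sine with the half-period stretched by 4 h."""
    return tmin + (tmax - tmin) * math.sin(math.pi * (h - sun.sunrise) / (sun.daylength + 4))


def _sunset_temp(tmin: float, tmax: float, sun: SolarTimes) -> float:
    return tmin + (tmax - tmin) * math.sin(math.pi * sun.daylength / (sun.daylength + 4))


def _night_curve(hours_past_sunset: float, t_sunset: float, tmin_next: float, nightlength: float) -> float:
    """Logarithmic cooling from the sunset temperature towards the next minimum."""
    if nightlength <= 1:
        return tmin_next
    frac = math.log(max(1.0, hours_past_sunset)) / math.log(nightlength)
    return t_sunset - (t_sunset - tmin_next) * frac


def make_hourly_temps(table: pd.DataFrame, latitude: float) -> pd.DataFrame:
    """Reconstruct hourly temperatures at integer hours 0-23 for every day.

    Requires a gap-free daily record.  The first and last days use their own
    Tmin where a neighbouring day's minimum would be needed.  Days with
    degenerate daylength (0 or 24 h after polar clipping) fall back to a
    linear Tmin-Tmax ramp and are flagged in the log.

    Returns a frame with columns Year, Month, Day, JDay, Hour, Temp.
    """
    if table[["Tmin", "Tmax"]].isna().any().any():
        raise ValueError("make_hourly_temps requires a gap-filled record (no missing Tmin/Tmax)")
    n = len(table)
    tmin = table["Tmin"].to_numpy(float)
    tmax = table["Tmax"].to_numpy(float)
    jday = table["JDay"].to_numpy(int)
    suns = [solar_times(int(j), latitude) for j in jday]
    temps = np.empty(n * 24)
    hours = np.tile(np.arange(24), n)
    for i in range(n):
        sun = suns[i]
        if sun.daylength <= 0 or sun.daylength >= 24:
            logger.warning(
                "make_hourly_temps: degenerate daylength %.1f h on row %d; linear ramp used",
                sun.daylength, i,
            )
            temps[i * 24 : (i + 1) * 24] = tmin[i] + (tmax[i] - tmin[i]) * np.arange(24) / 23.0
            continue
        prev = max(i - 1, 0)
        nxt = min(i + 1, n - 1)
        sun_prev = suns[prev]
        ts_prev = _sunset_temp(tmin[prev], tmax[prev], sun_prev)
        ts_here = _sunset_temp(tmin[i], tmax[i], sun)
        for h in range(24):
            if h < sun.sunrise:
                # tail of the previous night's decay towards today's Tmin
                temps[i * 24 + h] = _night_curve(
                    h + 24 - sun_prev.sunset, ts_prev, tmin[i], 24 - sun_prev.daylength
                )
            elif h <= sun.sunset:
                temps[i * 24 + h] = _day_curve(h, tmin[i], tmax[i], sun)
            else:
                temps[i * 24 + h] = _night_curve(
                    h - sun.sunset, ts_here, tmin[nxt], 24 - sun.daylength
                )
    out = pd.DataFrame(
        {
            "Year": np.repeat(table["Year"].to_numpy(int), 24),
            "Month": np.repeat(table["Month"].to_numpy(int), 24),
            "Day": np.repeat(table["Day"].to_numpy(int), 24),
            "JDay": np.repeat(jday, 24),
            "Hour": hours,
            "Temp": temps,
        }
    )
    if not np.isfinite(temps).all():
        raise ValueError("non-finite hourly temperature produced; check the daily record")
    return out
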