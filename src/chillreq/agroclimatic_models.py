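"""Hourly chill and heat accumulation models.

Four classic agroclimatic response models, all driven by hourly
temperature (degrees C):

* Chilling Hours (CH): one unit per hour with 0 <= T <= 7.2.
* Utah Chill Units (CU): weighted hours; moderate cold counts fully,
  marginal temperatures half, warm temperatures negatively.
* Chill Portions (CP, Dynamic Model): two-step kinetics in which a
  thermally labile precursor accumulates towards a threshold and is then
  banked irreversibly as a "portion"; the most robust metric under mild
  winters.
* Growing Degree Hours (GDH): sinusoidal heat response between base,
  optimum and critical temperatures.

All model functions take an array of hourly temperatures and return the
per-hour increment of the metric; running totals are cumulative sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DynamicModelConstants",
    "chilling_hours",
    "utah_units",
    "chill_portions",
    "gdh",
    "accumulation_table",
    "daily_chill",
    "runn_mean",
    "METRICS",
]

METRICS = ("CH", "CU", "CP", "GDH")


@dataclass(frozen=True)
class DynamicModelConstants:
    """Literature rate constants of the two-step Dynamic Model.

    ``slp`` and ``tetmlt`` (K) shape the temperature response of the
    portion-conversion step; ``a0``/``a1`` and ``e0``/``e1`` are the
    pre-exponential factors and activation energies (K) of the precursor
    formation/destruction reactions.
    """

    slp: float = 1.6
    tetmlt: float = 277.0
    a0: float = 1.395e5
    a1: float = 2.567e18
    e0: float = 4153.5
    e1: float = 12888.8


def _as_array(hourly) -> np.ndarray:
    if isinstance(hourly, pd.DataFrame):
        hourly = hourly["Temp"]
    arr = np.asarray(hourly, dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise ValueError("hourly temperatures must be finite")
    return arr


def chilling_hours(hourly) -> np.ndarray:
    """Hourly Chilling Hours increments: 1 when 0 <= T <= 7.2 degC."""
    t = _as_array(hourly)
    return ((t >= 0.0) & (t <= 7.2)).astype(float)


def utah_units(hourly) -> np.ndarray:
    """Hourly Utah Chill Unit increments (piecewise weights, upper bounds inclusive)."""
    t = _as_array(hourly)
    out = np.zeros_like(t)
    out[(t > 1.4) & (t <= 2.4)] = 0.5
    out[(t > 2.4) & (t <= 9.1)] = 1.0
    out[(t > 9.1) & (t <= 12.4)] = 0.5
    # (12.4, 15.9] stays 0
    out[(t > 15.9) & (t <= 18.0)] = -0.5
    out[t > 18.0] = -1.0
    return out


def chill_portions(hourly, constants: DynamicModelConstants = DynamicModelConstants()) -> np.ndarray:
    """Hourly Chill Portion increments from the Dynamic Model recurrence.

    Per hour, with TK = T + 273: the precursor level x relaxes towards its
    temperature-dependent equilibrium ``xs`` at rate ``ak1``; once x reaches
    1, a fraction ``xi`` (the conversion yield) is fixed as a portion and
    removed from the pool.  The intermediate starts at 0.
    """
    t = _as_array(hourly)
    n = t.size
    out = np.zeros(n)
    if n == 0:
        return out
    tk = t + 273.0
    c = constants
    ftmprt = c.slp * c.tetmlt * (tk - c.tetmlt) / tk
    sr = np.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = (c.a0 / c.a1) * np.exp((c.e1 - c.e0) / tk)
    ak1 = c.a1 * np.exp(-c.e1 / tk)
    decay = np.exp(-ak1)
    x = 0.0
    for i in range(n):
        x = xs[i] - (xs[i] - x) * decay[i]
        if not math.isfinite(x):
            raise ValueError(f"non-finite Dynamic Model intermediate at hour {i}")
        if x >= 1.0:
            delta = x * xi[i]
            out[i] = delta
            x -= delta
    return out


def gdh(hourly, base: float = 4.0, optimum: float = 25.0, critical: float = 36.0) -> np.ndarray:
    """Hourly Growing Degree Hour increments (sinusoidal base/optimum/critical curve)."""
    if not base < optimum < critical:
        raise ValueError("GDH parameters must satisfy base < optimum < critical")
    t = _as_array(hourly)
    out = np.zeros_like(t)
    rising = (t > base) & (t <= optimum)
    falling = (t > optimum) & (t <= critical)
    out[rising] = ((optimum - base) / 2.0) * (
        1.0 + np.cos(np.pi + np.pi * (t[rising] - base) / (optimum - base))
    )
    out[falling] = (optimum - base) * (
        1.0 + np.cos(np.pi / 2.0 + (np.pi / 2.0) * (t[falling] - optimum) / (critical - optimum))
    )
    return out


def accumulation_table(hourly: pd.DataFrame, constants: DynamicModelConstants = DynamicModelConstants()) -> pd.DataFrame:
    """Hourly increments and running totals of every metric, aligned with ``hourly``."""
    out = hourly.copy()
    for name, series in (
        ("CH", chilling_hours(hourly)),
        ("CU", utah_units(hourly)),
        ("CP", chill_portions(hourly, constants)),
        ("GDH", gdh(hourly)),
    ):
        out[name] = series
        out[f"{name}_total"] = np.cumsum(series)
    return out


def runn_mean(values, window: int) -> np.ndarray:
    """Centred running mean of odd width ``window``, truncated at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    if window == 1 or x.size == 0:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def daily_chill(
    hourly: pd.DataFrame,
    smoothing_window: int = 1,
    constants: DynamicModelConstants = DynamicModelConstants(),
) -> pd.DataFrame:
    """Daily increments of every metric, optionally smoothed by a running mean.

    Rows are calendar days in record order (Year, Month, Day, JDay).  Raw
    daily increments always sum to the hourly running total over the same
    span; smoothed columns (suffix ``_smoothed``) apply :func:`runn_mean`
    over the whole record and are added only when ``smoothing_window > 1``.
    """
    acc = accumulation_table(hourly, constants)
    daily = (
        acc.groupby(["Year", "Month", "Day"], sort=False, as_index=False)
        .agg({"JDay": "first", **{m: "sum" for m in METRICS}})
    )
    daily = daily[["Year", "Month", "Day", "JDay", *METRICS]]
    if smoothing_window > 1:
        for m in METRICS:
            daily[f"{m}_smoothed"] = runn_mean(daily[m].to_numpy(), smoothing_window)
    return daily
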