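"""Synthetic weather and progeny generators with known ground truth.

Real chilling-requirement studies rely on decades of orchard records that
cannot ship with a package.  These generators emulate both inputs at a
Mediterranean-like site: daily temperature extremes follow a seasonal
sinusoid with AR(1) day-to-day noise, and progeny bloom dates arise from
the same sequential chill-then-heat phenology the PLS delineation assumes
— each genotype accumulates Chill Portions from a fixed autumn start day
until its genotype-specific chilling requirement (CR) is met (dormancy
release), then accumulates Growing Degree Hours until its heat requirement
is met (bloom).  Because the true CR and release day of every genotype are
known, pipeline runs on these data support parameter-recovery tests.

Seasons in which the CR is never met are recorded with the invalid
marker (*), exercising the same filtering pathway as field data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._calendar import day_index, index_to_date
from .agroclimatic_models import DynamicModelConstants, chill_portions, gdh
from .io_phenology import INVALID_MARKER
from .weather import make_hourly_temps

__all__ = ["WeatherSimParams", "ProgenySimParams", "simulate_weather", "simulate_progeny"]


@dataclass(frozen=True)
class WeatherSimParams:
    """Seasonal-sinusoid daily weather generator settings.

    Defaults emulate a mild-winter Mediterranean orchard site (the setting
    in which Dynamic-Model chill accounting matters most), calibrated to a
    southeastern-Spain inland orchard: mid-winter daily mean near 10 degC,
    a 12 degC diurnal range, day-to-day anomaly sd of 1.7 degC, and a
    seasonal chill yield of roughly 60-75 Chill Portions.
    """

    latitude: float = 38.11
    first_year: int = 2011
    last_year: int = 2025
    annual_mean: float = 17.5       # degC
    annual_amplitude: float = 7.6   # degC, half peak-to-trough of the seasonal cycle
    diurnal_range: float = 11.9     # degC, tmax - tmin
    noise_sd: float = 1.7           # degC, stationary sd of daily anomalies
    autocorr: float = 0.65          # AR(1) coefficient of daily anomalies
    coldest_doy: int = 15           # day of year of the seasonal minimum
    seed: int = 0


@dataclass(frozen=True)
class ProgenySimParams:
    """Progeny bloom generator settings.

    CR is drawn per genotype in Chill Portions and the heat requirement in
    GDH; defaults span the range reported for apricot crosses between low-
    and high-chill parents.  Chill counting starts on Nov 1 (season-day
    index -60), consistent with first portions appearing in early November
    at mild-winter sites.
    """

    n_genotypes: int = 20
    cr_mean: float = 30.0           # chill portions
    cr_sd: float = 8.0
    heat_mean: float = 5500.0       # growing degree hours
    heat_sd: float = 800.0
    chill_start_index: int = -60    # season-day index of chill onset (Nov 1)
    bloom_noise_sd: float = 1.5     # days; observation noise on bloom DOY
    season_end_doy: int = 181       # Jun 30; CR/heat unmet by then -> invalid marker
    seed: int = 0


def simulate_weather(params: WeatherSimParams = WeatherSimParams()) -> pd.DataFrame:
    """Generate a gap-free daily weather table (Day, JDay, Month, Year, Tmax, Tmin).

    Daily mean = annual_mean - annual_amplitude * cos(2 pi (doy - coldest_doy)/365)
    plus a stationary AR(1) anomaly; Tmin/Tmax sit half the diurnal range
    below/above the daily mean, so Tmax > Tmin always holds.  Same seed,
    same record.
    """
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(
        f"{params.first_year}-01-01", f"{params.last_year}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy()
    tmean = params.annual_mean - params.annual_amplitude * np.cos(
        2 * np.pi * (doy - params.coldest_doy) / 365.0
    )
    n = len(dates)
    noise = np.zeros(n)
    if params.noise_sd > 0:
        innov_sd = params.noise_sd * np.sqrt(1.0 - params.autocorr**2)
        eps = rng.normal(0.0, innov_sd, n)
        noise[0] = rng.normal(0.0, params.noise_sd)
        for i in range(1, n):
            noise[i] = params.autocorr * noise[i - 1] + eps[i]
    tmean = tmean + noise
    half = params.diurnal_range / 2.0
    return pd.DataFrame(
        {
            "Day": dates.day,
            "JDay": doy,
            "Month": dates.month,
            "Year": dates.year,
            "Tmax": np.round(tmean + half, 2),
            "Tmin": np.round(tmean - half, 2),
        }
    )


def simulate_progeny(
    weather: pd.DataFrame,
    params: ProgenySimParams = ProgenySimParams(),
    latitude: float = 38.11,
    seasons: list[int] | None = None,
    constants: DynamicModelConstants = DynamicModelConstants(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a wide bloom table and its ground truth from weather.

    Per genotype and season: Chill Portions accumulate hourly from the
    chill start day; the day the running total reaches the genotype's CR
    is the true dormancy-release day.  GDH then accumulate from the next
    hour; bloom falls on the day the heat requirement is met (never
    earlier than the day after release), plus optional Gaussian noise,
    rounded to a whole DOY.  Seasons where CR or heat is not met by the
    season end get the invalid marker.

    Returns ``(bloom_wide, ground_truth)``; the bloom table follows the
    Genotype/BDyy layout, the ground truth lists the true CR, heat
    requirement, release day and bloom day per genotype x season.
    """
    rng = np.random.default_rng(params.seed)
    cr = np.maximum(1.0, rng.normal(params.cr_mean, params.cr_sd, params.n_genotypes))
    heat = np.maximum(100.0, rng.normal(params.heat_mean, params.heat_sd, params.n_genotypes))
    genotypes = [f"1_{i + 1}" for i in range(params.n_genotypes)]

    hourly = make_hourly_temps(weather, latitude)
    cp_inc = chill_portions(hourly, constants)
    gdh_inc = gdh(hourly)
    hour_dates = pd.to_datetime(
        dict(year=hourly["Year"], month=hourly["Month"], day=hourly["Day"])
    ).dt.date.to_numpy()

    years = sorted(weather["Year"].unique())
    if seasons is None:
        seasons = [y for y in years if y - 1 in years]
    season_slices = {}
    for season in seasons:
        start = index_to_date(params.chill_start_index, season)
        end = index_to_date(params.season_end_doy, season)
        mask = (hour_dates >= start) & (hour_dates <= end)
        n_days = (end - start).days + 1
        if int(mask.sum()) != 24 * n_days:
            raise ValueError(f"weather does not fully cover season {season}")
        season_slices[season] = np.flatnonzero(mask)

    wide_cells: dict[str, dict[str, object]] = {g: {} for g in genotypes}
    truth_rows = []
    noise = rng.normal(0.0, params.bloom_noise_sd, (params.n_genotypes, len(seasons)))
    for gi, genotype in enumerate(genotypes):
        for si, season in enumerate(seasons):
            col = f"BD{str(season)[-2:]}"
            idx = season_slices[season]
            cp_cum = np.cumsum(cp_inc[idx])
            reached = np.flatnonzero(cp_cum >= cr[gi])
            if reached.size == 0:
                wide_cells[genotype][col] = INVALID_MARKER
                truth_rows.append((genotype, season, cr[gi], heat[gi], None, None, None))
                continue
            release_hour = reached[0]
            release_day = day_index(hour_dates[idx[release_hour]], season)
            gdh_cum = np.cumsum(gdh_inc[idx[release_hour + 1 :]])
            met = np.flatnonzero(gdh_cum >= heat[gi])
            if met.size == 0:
                wide_cells[genotype][col] = INVALID_MARKER
                truth_rows.append((genotype, season, cr[gi], heat[gi], release_day, None, None))
                continue
            bloom_date = hour_dates[idx[release_hour + 1 + met[0]]]
            true_bloom = max(day_index(bloom_date, season), release_day + 1)
            observed = max(int(round(true_bloom + (noise[gi, si] if params.bloom_noise_sd > 0 else 0.0))),
                           release_day + 1)
            if observed < 1:
                # bloom before Jan 1 cannot be recorded as a season DOY
                wide_cells[genotype][col] = INVALID_MARKER
                truth_rows.append((genotype, season, cr[gi], heat[gi], release_day, true_bloom, None))
                continue
            wide_cells[genotype][col] = observed
            truth_rows.append((genotype, season, cr[gi], heat[gi], release_day, true_bloom, observed))

    columns = [f"BD{str(s)[-2:]}" for s in seasons]
    bloom_wide = pd.DataFrame(
        [[g, *[wide_cells[g].get(c, INVALID_MARKER) for c in columns]] for g in genotypes],
        columns=["Genotype", *columns],
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["Genotype", "Season", "TrueCR", "TrueHeatReq", "ReleaseDay", "TrueBloomDOY", "ObservedBloomDOY"],
    )
    return bloom_wide, ground_truth
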