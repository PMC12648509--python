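"""PLS regression of bloom dates on daily chill/heat and chill-window delineation.

For each genotype, bloom day of year is regressed on the season-aligned
daily chill accumulation series (and, by default, a parallel heat block of
daily GDH) via partial least squares (PLS), a latent-component method
suited to the many-collinear-predictors / few-seasons setting.  Days on
which extra chill advances bloom show negative model coefficients; the
Variable Importance in the Projection (VIP) score separates influential
days from noise.  The effective chilling period is the span from the first
to the last day with a negative coefficient and VIP >= 0.8, capped to end
at least one day before the genotype's median bloom date (chill cannot
meaningfully accrue once the tree has bloomed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from ._calendar import index_to_date, season_day_indices
from .io_phenology import BloomRecord

__all__ = [
    "SeasonMatrix",
    "PLSFit",
    "ChillWindow",
    "SampleSizeError",
    "WindowUndefinedError",
    "build_season_matrix",
    "fit_pls",
    "vip_scores",
    "day_results",
    "delineate_chill_window",
]

logger = logging.getLogger(__name__)

MIN_SEASONS = 4


class SampleSizeError(ValueError):
    """Too few usable seasons to fit a PLS model."""


class WindowUndefinedError(RuntimeError):
    """No day qualifies for the chilling window of a genotype."""

    def __init__(self, genotype: str, message: str):
        super().__init__(message)
        self.genotype = genotype


@dataclass
class SeasonMatrix:
    """Predictor blocks and response for one genotype's PLS fit.

    Rows are bloom seasons; columns are season-relative day indices
    (negative before Jan 1).  ``chill`` holds the smoothed daily increments
    of the chosen chill metric, ``heat`` the smoothed daily GDH (or None
    when the heat block is disabled); ``y`` is the bloom DOY per season.
    """

    genotype: str
    chill: pd.DataFrame
    heat: pd.DataFrame | None
    y: pd.Series
    chill_metric: str = "CP"
    dropped_seasons: list[int] = field(default_factory=list)

    @property
    def day_index(self) -> np.ndarray:
        return self.chill.columns.to_numpy(int)


@dataclass
class PLSFit:
    """Fitted PLS model mapped back to per-day coefficients and VIP scores.

    Coefficients are on the original predictor scale (days of bloom shift
    per unit daily increment); ``vip`` and internals refer to the included
    (non-constant) standardized columns.
    """

    matrix: SeasonMatrix
    n_components: int
    columns: list[tuple[str, int]]          # (block, day index) of all columns
    included: np.ndarray                    # boolean mask over columns
    coefficients: np.ndarray                # per column, original scale; 0 for excluded
    vip: np.ndarray                         # per column; 0 for excluded
    x_weights: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    fitted: np.ndarray


@dataclass(frozen=True)
class ChillWindow:
    """Season-relative span of a genotype's effective chilling period."""

    genotype: str
    start: int
    end: int
    capped: bool
    n_days: int


def build_season_matrix(
    daily: pd.DataFrame,
    bloom: list[BloomRecord],
    split_month: int = 11,
    end_day: int = 120,
    chill_metric: str = "CP",
    heat_block: bool = True,
    smoothing_window: int = 11,
) -> SeasonMatrix:
    """Assemble the per-season predictor matrix for one genotype.

    ``daily`` is the whole-record output of
    :func:`~chillreq.agroclimatic_models.daily_chill` (raw increments).
    Each bloom season contributes one row spanning the first day of
    ``split_month`` in the previous year through DOY ``end_day``; the
    chosen metric and GDH are smoothed per season by a centred running
    mean.  Seasons without complete weather coverage are dropped with a
    warning; fewer than four usable seasons is an error.
    """
    from .agroclimatic_models import runn_mean

    if not bloom:
        raise SampleSizeError("no bloom records supplied")
    genotype = bloom[0].genotype
    idx_grid = season_day_indices(split_month, end_day)
    dated = daily.copy()
    dated["date"] = pd.to_datetime(
        dict(year=daily["Year"], month=daily["Month"], day=daily["Day"])
    ).dt.date
    by_date = dated.set_index("date")

    chill_rows, heat_rows, y_vals, seasons, dropped = [], [], [], [], []
    for rec in sorted(bloom, key=lambda r: r.year):
        dates = [index_to_date(i, rec.year) for i in idx_grid]
        try:
            span = by_date.loc[dates]
        except KeyError:
            dropped.append(rec.year)
            logger.warning(
                "genotype %s: season %d lacks complete weather coverage; row dropped",
                genotype, rec.year,
            )
            continue
        chill_rows.append(runn_mean(span[chill_metric].to_numpy(), smoothing_window))
        if heat_block:
            heat_rows.append(runn_mean(span["GDH"].to_numpy(), smoothing_window))
        y_vals.append(rec.pheno)
        seasons.append(rec.year)
    if len(seasons) < MIN_SEASONS:
        raise SampleSizeError(
            f"genotype {genotype}: only {len(seasons)} usable season(s); "
            f"at least {MIN_SEASONS} required for PLS"
        )
    chill = pd.DataFrame(np.vstack(chill_rows), index=seasons, columns=idx_grid)
    heat = (
        pd.DataFrame(np.vstack(heat_rows), index=seasons, columns=idx_grid)
        if heat_block
        else None
    )
    y = pd.Series(y_vals, index=seasons, name="pheno", dtype=float)
    return SeasonMatrix(genotype, chill, heat, y, chill_metric, dropped)


def fit_pls(matrix: SeasonMatrix, n_components: int = 2) -> PLSFit:
    """Fit PLS of bloom DOY on the standardized predictor blocks.

    Columns are centred and scaled to unit variance (sample sd); constant
    columns are excluded from the fit (coefficient and VIP reported as 0).
    Coefficients are mapped back to the original predictor scale, which
    preserves their sign.
    """
    blocks = [("chill", matrix.chill)]
    if matrix.heat is not None:
        blocks.append(("heat", matrix.heat))
    X = np.hstack([b.to_numpy(float) for _, b in blocks])
    columns = [(name, int(day)) for name, b in blocks for day in b.columns]
    y = matrix.y.to_numpy(float)
    n, p = X.shape
    if n < n_components + 1:
        raise SampleSizeError(
            f"genotype {matrix.genotype}: {n} season(s) cannot support "
            f"{n_components} PLS component(s)"
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    included = std > 0
    if not included.any():
        raise ValueError(
            f"genotype {matrix.genotype}: all predictor columns are constant"
        )
    n_excluded = int((~included).sum())
    if n_excluded:
        logger.info(
            "genotype %s: %d constant column(s) excluded from PLS",
            matrix.genotype, n_excluded,
        )
    Z = (X[:, included] - mean[included]) / std[included]
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(Z, y)
    coef_std = model.coef_.reshape(-1)
    coefficients = np.zeros(p)
    coefficients[included] = coef_std / std[included]
    fitted = model.predict(Z).reshape(-1)
    fit = PLSFit(
        matrix=matrix,
        n_components=n_components,
        columns=columns,
        included=included,
        coefficients=coefficients,
        vip=np.zeros(p),
        x_weights=model.x_weights_,
        x_scores=model.x_scores_,
        y_loadings=model.y_loadings_,
        x_mean=mean,
        x_std=std,
        fitted=fitted,
    )
    fit.vip[included] = vip_scores(fit)
    return fit


def vip_scores(fit: PLSFit) -> np.ndarray:
    """Variable Importance in the Projection for the included columns.

    VIP_j = sqrt(p * sum_a SS_a (w_aj/||w_a||)^2 / sum_a SS_a) with
    SS_a = q_a^2 t_a' t_a, so the mean squared VIP over included columns
    is exactly 1.
    """
    W = fit.x_weights
    T = fit.x_scores
    q = fit.y_loadings.reshape(-1)
    ss = q**2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = W**2 / (W**2).sum(axis=0)
    p = W.shape[0]
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def day_results(fit: PLSFit) -> pd.DataFrame:
    """Per-day PLS output table: day index, VIP, coefficient, metric mean/sd.

    One row per predictor column; the ``Block`` column distinguishes the
    chill metric from the heat (GDH) block.  Mean and sd are across seasons
    of the smoothed daily values the model was fitted on.
    """
    return pd.DataFrame(
        {
            "Block": [b for b, _ in fit.columns],
            "Day": [d for _, d in fit.columns],
            "VIP": fit.vip,
            "Coef": fit.coefficients,
            "MetricMean": fit.x_mean,
            "MetricSd": fit.x_std,
        }
    )


def delineate_chill_window(
    results: pd.DataFrame,
    median_bloom: float,
    genotype: str = "",
    vip_threshold: float = 0.8,
    min_run: int = 3,
) -> ChillWindow:
    """Delineate the chilling period from per-day VIP scores and coefficients.

    A day qualifies when its VIP is at or above ``vip_threshold`` and its
    coefficient is negative, restricted to the chill block.  Qualifying
    days must belong to a series of at least ``min_run`` consecutive day
    indices: the endodormancy phase is a sustained negative-coefficient
    span, and with smoothed predictors spurious qualifiers arrive in short
    correlated clusters, so isolated days are discarded (``min_run=1``
    recovers the permissive every-qualifier reading).  Chill accumulation
    cannot meaningfully extend past bloom, so days beyond
    floor(median_bloom - 1) are then removed; the window spans the first
    to the last remaining day and is flagged capped when the bloom rule
    shortened it.
    """
    chill = results[results["Block"] == "chill"]
    qualifying = chill.loc[(chill["VIP"] >= vip_threshold) & (chill["Coef"] < 0), "Day"]
    days = sorted(int(d) for d in qualifying)
    if min_run > 1 and days:
        runs, current = [], [days[0]]
        for d in days[1:]:
            if d == current[-1] + 1:
                current.append(d)
            else:
                runs.append(current)
                current = [d]
        runs.append(current)
        days = [d for run in runs if len(run) >= min_run for d in run]
    if not days:
        raise WindowUndefinedError(
            genotype,
            f"genotype {genotype or '<unknown>'}: no day with VIP >= {vip_threshold}, "
            f"a negative chill coefficient and a run of >= {min_run} such days",
        )
    cap = math.floor(median_bloom - 1)
    raw_end = days[-1]
    days = [d for d in days if d <= cap]
    if not days:
        raise WindowUndefinedError(
            genotype,
            f"genotype {genotype or '<unknown>'}: every qualifying day falls on or "
            f"after the median bloom cap ({cap})",
        )
    return ChillWindow(
        genotype=genotype,
        start=days[0],
        end=days[-1],
        capped=raw_end > cap,
        n_days=len(days),
    )
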