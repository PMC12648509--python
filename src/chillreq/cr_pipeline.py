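"""End-to-end chilling-requirement workflow and output compilation.

Runs, per genotype: bloom-table filtering and reshaping, weather QC and
hourly reconstruction, daily chill accumulation, PLS delineation of the
chilling window, and accumulation of Chilling Hours, Utah Chill Units and
Chill Portions over that window in every season.  The final product is a
wide chilling-requirement (CR) table, one row per genotype with one
column per season x metric, the standardized phenotype format used
downstream (e.g. for QTL mapping).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._calendar import index_to_date
from .agroclimatic_models import DynamicModelConstants, accumulation_table, daily_chill
from .io_phenology import (
    BloomRecord,
    filter_invalid,
    parse_genotype_id,
    read_bloom_wide,
    split_by_genotype,
    wide_to_long,
)
from .pls_delineation import (
    ChillWindow,
    SampleSizeError,
    WindowUndefinedError,
    build_season_matrix,
    day_results,
    delineate_chill_window,
    fit_pls,
)
from .weather import fix_weather, make_hourly_temps, read_weather, trim_to_period

__all__ = [
    "CREstimate",
    "PipelineConfig",
    "median_bloom",
    "season_chill_accumulation",
    "compile_cr_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CR_METRICS = ("CH", "CU", "CP")


@dataclass(frozen=True)
class CREstimate:
    """Chill accumulated over one genotype's window in one season."""

    genotype: str
    season: int
    ch: float | None
    cu: float | None
    cp: float | None


@dataclass
class PipelineConfig:
    """All knobs of the workflow; defaults follow the standard protocol."""

    bloom_files: list[str | Path]
    weather_file: str | Path
    latitude: float
    out_dir: str | Path
    split_month: int = 11          # dormant season starts in November
    end_day: int = 120             # predictor window ends at DOY 120 (Apr 30)
    vip_threshold: float = 0.8
    n_components: int = 2
    runn_mean: int = 11            # smoothing window (days) for daily series
    chill_metric: str = "CP"
    heat_block: bool = True
    invalid_policy: str = "drop-genotype"
    seasons: list[int] | None = None   # seasons of interest; None = all in bloom data
    century: int = 20
    max_gap: int = 30
    min_run: int = 3
    seed: int = 0                  # recorded in the manifest; pipeline itself is deterministic
    dynamic_constants: DynamicModelConstants = field(default_factory=DynamicModelConstants)


def median_bloom(records: list[BloomRecord]) -> float:
    """Median bloom DOY of a genotype (midpoint of the two central values when even)."""
    if not records:
        raise ValueError("median_bloom requires at least one record")
    return float(statistics.median(r.pheno for r in records))


def season_chill_accumulation(
    hourly_acc: pd.DataFrame,
    window: ChillWindow,
    season: int,
) -> CREstimate:
    """Accumulate CH/CU/CP over the window's hours in one season.

    ``hourly_acc`` is the output of
    :func:`~chillreq.agroclimatic_models.accumulation_table`.  The span
    runs from 00:00 of the window start day through 23:00 of the end day,
    with day indices mapped to calendar dates via the season-relative
    convention.  Incomplete hourly coverage marks the cell missing.
    """
    start_date = index_to_date(window.start, season)
    end_date = index_to_date(window.end, season)
    dates = pd.to_datetime(
        dict(year=hourly_acc["Year"], month=hourly_acc["Month"], day=hourly_acc["Day"])
    ).dt.date
    mask = (dates >= start_date) & (dates <= end_date)
    n_days = (end_date - start_date).days + 1
    if int(mask.sum()) != 24 * n_days:
        logger.warning(
            "genotype %s, season %d: hourly record covers %d of %d hours in the "
            "chill window; cell marked missing",
            window.genotype, season, int(mask.sum()), 24 * n_days,
        )
        return CREstimate(window.genotype, season, None, None, None)
    span = hourly_acc.loc[mask]
    return CREstimate(
        genotype=window.genotype,
        season=season,
        ch=float(span["CH"].sum()),
        cu=float(span["CU"].sum()),
        cp=float(span["CP"].sum()),
    )


def compile_cr_table(
    estimates: list[CREstimate],
    seasons_of_interest: list[int],
    summary: bool = True,
) -> pd.DataFrame:
    """Pivot per-season estimates to the wide CR table.

    One row per genotype (input order preserved); columns are
    ``<metric>_<season>`` for each season of interest, metric order CH,
    CU, CP.  Missing genotype-season cells stay empty.  When ``summary``
    is on, derived across-season mean and sd columns are appended per
    metric (the per-season values are the primary output).
    """
    genotypes = list(dict.fromkeys(e.genotype for e in estimates))
    seasons = sorted(seasons_of_interest)
    columns = [f"{m}_{s}" for s in seasons for m in CR_METRICS]
    table = pd.DataFrame(index=genotypes, columns=columns, dtype=float)
    for e in estimates:
        if e.season not in seasons:
            continue
        for metric, value in zip(CR_METRICS, (e.ch, e.cu, e.cp)):
            if value is not None:
                table.loc[e.genotype, f"{metric}_{e.season}"] = value
    if summary:
        for m in CR_METRICS:
            cols = [f"{m}_{s}" for s in seasons]
            values = table[cols]
            table[f"{m}_mean"] = values.mean(axis=1)
            table[f"{m}_sd"] = values.std(axis=1, ddof=1)
    table.insert(0, "Genotype", table.index)
    return table.reset_index(drop=True)


def _season_summary(estimates: list[CREstimate], records: list[BloomRecord]) -> pd.DataFrame:
    """Per-season distribution summary of bloom dates and CR metrics (simple export)."""
    bloom = pd.DataFrame([(r.year, r.pheno) for r in records], columns=["Season", "pheno"])
    est = pd.DataFrame(
        [(e.season, e.ch, e.cu, e.cp) for e in estimates],
        columns=["Season", "CH", "CU", "CP"],
    )
    merged = est.merge(bloom.groupby("Season")["pheno"].mean().rename("BloomMean"), on="Season")
    summary = merged.groupby("Season").agg(
        n=("CH", "size"),
        BloomMean=("BloomMean", "first"),
        CH_mean=("CH", "mean"), CH_sd=("CH", "std"),
        CU_mean=("CU", "mean"), CU_sd=("CU", "std"),
        CP_mean=("CP", "mean"), CP_sd=("CP", "std"),
    )
    return summary.reset_index()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow and write all outputs to ``config.out_dir``.

    Writes, under the output directory: one per-genotype PLS day-result
    file, the compiled CR table (CSV and XLSX), a QC report, a per-season
    distribution summary, a report of genotypes whose window could not be
    delineated (not fatal), and a run manifest with every parameter.
    Identical inputs and configuration give byte-identical CSV outputs.
    """
    out_dir = Path(config.out_dir)
    pls_dir = out_dir / "pls"
    out_dir.mkdir(parents=True, exist_ok=True)
    pls_dir.mkdir(exist_ok=True)

    # --- phenology ---
    all_records: list[BloomRecord] = []
    for bloom_file in config.bloom_files:
        try:
            wide = read_bloom_wide(bloom_file)
        except FileNotFoundError as err:
            raise FileNotFoundError(f"bloom stage: cannot read {bloom_file}") from err
        wide = filter_invalid(wide, config.invalid_policy)
        all_records.extend(wide_to_long(wide, century=config.century))
    if not all_records:
        raise ValueError("bloom stage: no valid bloom records after filtering")
    groups = split_by_genotype(all_records)

    # --- weather ---
    try:
        weather_daily = read_weather(config.weather_file)
    except FileNotFoundError as err:
        raise FileNotFoundError(f"weather stage: cannot read {config.weather_file}") from err
    weather_daily = trim_to_period(weather_daily, all_records)
    weather_daily, qc = fix_weather(weather_daily, max_gap=config.max_gap)
    hourly = make_hourly_temps(weather_daily, config.latitude)
    hourly_acc = accumulation_table(hourly, config.dynamic_constants)
    daily = daily_chill(hourly, constants=config.dynamic_constants)

    # --- per-genotype PLS delineation and window accumulation ---
    estimates: list[CREstimate] = []
    undefined: list[dict] = []
    windows: dict[str, ChillWindow] = {}
    for genotype, records in groups.items():
        gid = parse_genotype_id(genotype)
        try:
            matrix = build_season_matrix(
                daily,
                records,
                split_month=config.split_month,
                end_day=config.end_day,
                chill_metric=config.chill_metric,
                heat_block=config.heat_block,
                smoothing_window=config.runn_mean,
            )
            fit = fit_pls(matrix, n_components=config.n_components)
        except SampleSizeError as err:
            undefined.append({"Genotype": genotype, "Reason": str(err)})
            logger.warning("%s", err)
            continue
        results = day_results(fit)
        results.to_csv(pls_dir / f"pls_{gid.group1}_{gid.group2}.csv", index=False)
        try:
            window = delineate_chill_window(
                results,
                median_bloom(records),
                genotype=genotype,
                vip_threshold=config.vip_threshold,
                min_run=config.min_run,
            )
        except WindowUndefinedError as err:
            undefined.append({"Genotype": genotype, "Reason": str(err)})
            logger.warning("%s", err)
            continue
        windows[genotype] = window
        for rec in sorted(records, key=lambda r: r.year):
            estimates.append(season_chill_accumulation(hourly_acc, window, rec.year))

    # --- compile outputs ---
    seasons = config.seasons or sorted({r.year for r in all_records})
    cr_table = compile_cr_table(estimates, seasons)
    cr_table.to_csv(out_dir / "cr_table.csv", index=False)
    cr_table.to_excel(out_dir / "cr_table.xlsx", index=False)
    pd.DataFrame(
        [
            {
                "Genotype": g,
                "Start": w.start,
                "End": w.end,
                "Capped": w.capped,
                "QualifyingDays": w.n_days,
            }
            for g, w in windows.items()
        ]
    ).to_csv(out_dir / "chill_windows.csv", index=False)
    pd.DataFrame(undefined, columns=["Genotype", "Reason"]).to_csv(
        out_dir / "undefined_windows.csv", index=False
    )
    _season_summary(estimates, all_records).to_csv(out_dir / "season_summary.csv", index=False)
    (out_dir / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=2))
    (out_dir / "qc_report.txt").write_text(
        "Weather QC report\n"
        f"  date range: {qc.date_range[0]} .. {qc.date_range[1]}\n"
        f"  missing Tmin: {qc.n_missing_tmin}  missing Tmax: {qc.n_missing_tmax}  "
        f"missing days: {qc.n_missing_days}\n"
        f"  interpolated days: {len(qc.interpolated_days)}\n"
        + "".join(f"  FLAG: {f}\n" for f in qc.flags)
    )
    manifest = {
        "chillreq_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {
            k: (str(v) if isinstance(v, (Path,)) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "dynamic_constants"
        },
        "dynamic_constants": dataclasses.asdict(config.dynamic_constants),
        "n_genotypes": len(groups),
        "n_windows": len(windows),
        "n_undefined": len(undefined),
    }
    manifest["config"]["bloom_files"] = [str(p) for p in config.bloom_files]
    manifest["config"]["weather_file"] = str(config.weather_file)
    manifest["config"]["out_dir"] = str(config.out_dir)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info(
        "run_pipeline: %d genotypes, %d windows delineated, %d undefined; outputs in %s",
        len(groups), len(windows), len(undefined), out_dir,
    )
    return out_dir
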