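"""Reading, validating and reshaping bloom-date tables.

Breeding programmes record one full-bloom date (day of year, DOY) per
genotype and growing season in a wide table: a ``Genotype`` column followed
by ``BDyy`` season columns, where ``yy`` is the two-digit year.  Seasons in
which no reliable date could be assigned (very poor flowering) are marked
with an asterisk.  This module parses that layout, filters invalid entries,
melts the table to one record per genotype x season, and splits records by
genotype for the per-genotype regression stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "BloomRecord",
    "GenotypeId",
    "SchemaError",
    "ParseError",
    "IdentifierError",
    "INVALID_MARKER",
    "read_bloom_wide",
    "write_bloom_wide",
    "filter_invalid",
    "wide_to_long",
    "long_to_wide",
    "records_to_frame",
    "parse_genotype_id",
    "split_by_genotype",
]

logger = logging.getLogger(__name__)

INVALID_MARKER = "*"
_BD_COLUMN = re.compile(r"^BD(\d{2})$")
_GENOTYPE_ID = re.compile(r"^(\d+)_(\d+)$")


class SchemaError(ValueError):
    """Input table does not follow the expected column layout."""


class ParseError(ValueError):
    """A cell could not be parsed as a bloom DOY or invalid marker."""


class IdentifierError(ValueError):
    """A genotype identifier does not follow the ``<int>_<int>`` pattern."""


@dataclass(frozen=True, order=True)
class BloomRecord:
    """One genotype x season bloom observation."""

    genotype: str
    year: int
    pheno: int  # bloom day of year


@dataclass(frozen=True)
class GenotypeId:
    raw: str
    group1: int  # number before the underscore
    group2: int  # number after the underscore


def _validate_wide_columns(columns: list[str]) -> None:
    if not columns or columns[0] != "Genotype":
        raise SchemaError("first column must be named 'Genotype'")
    for col in columns[1:]:
        if not _BD_COLUMN.match(str(col)):
            raise SchemaError(f"season column {col!r} does not match pattern 'BDyy'")


def _parse_cells(table: pd.DataFrame, source: object) -> pd.DataFrame:
    """Coerce season cells to nullable integers; '*' and blanks become missing."""
    out = table.copy()
    for col in out.columns[1:]:
        parsed = []
        for row_pos, cell in enumerate(out[col]):
            if pd.isna(cell) or str(cell).strip() in ("", INVALID_MARKER):
                parsed.append(pd.NA)
                continue
            text = str(cell).strip()
            try:
                doy = int(float(text)) if float(text).is_integer() else None
            except ValueError:
                doy = None
            if doy is None or not 1 <= doy <= 366:
                raise ParseError(
                    f"{source}: cell {text!r} at row {row_pos}, column {col!r} "
                    "is not a bloom DOY in [1, 366] or the invalid marker"
                )
            parsed.append(doy)
        out[col] = pd.array(parsed, dtype="Int64")
    out["Genotype"] = out["Genotype"].astype(str)
    return out


def read_bloom_wide(source: str | Path | pd.DataFrame, sheet: str | int = 0) -> pd.DataFrame:
    """Read a wide bloom table (Genotype, BDyy...) from CSV, XLSX or a frame.

    Cells are parsed to nullable integer DOY; the asterisk marker and empty
    cells both become missing.  Column order is preserved.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xls"):
            raw = pd.read_excel(path, sheet_name=sheet, dtype=str)
        else:
            raw = pd.read_csv(path, dtype=str)
    _validate_wide_columns(list(raw.columns))
    return _parse_cells(raw, source if not isinstance(source, pd.DataFrame) else "<frame>")


def write_bloom_wide(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wide bloom table to CSV or XLSX, missing cells left empty."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False)


def filter_invalid(table: pd.DataFrame, policy: str = "drop-genotype") -> pd.DataFrame:
    """Remove invalid/missing bloom entries.

    ``drop-genotype`` removes every genotype whose row has any missing or
    marked cell (the conservative whole-row filter used when a marker casts
    doubt on the genotype's record); ``drop-observation`` keeps the genotype
    and blanks only the affected season cells.
    """
    season_cols = table.columns[1:]
    if policy == "drop-genotype":
        mask = table[season_cols].notna().all(axis=1)
        removed = int((~mask).sum())
        out = table.loc[mask].reset_index(drop=True)
        logger.info("filter_invalid: dropped %d genotype(s) with invalid/missing cells", removed)
        return out
    if policy == "drop-observation":
        n_blank = int(table[season_cols].isna().sum().sum())
        logger.info("filter_invalid: %d invalid/missing cell(s) left blank", n_blank)
        return table.copy()
    raise ValueError(f"unknown invalid-entry policy {policy!r}")


def wide_to_long(table: pd.DataFrame, century: int = 20) -> list[BloomRecord]:
    """Melt a wide bloom table to records; 'BDyy' maps to year century*100+yy."""
    records = []
    for _, row in table.iterrows():
        genotype = str(row["Genotype"])
        for col in table.columns[1:]:
            if pd.isna(row[col]):
                continue
            yy = int(_BD_COLUMN.match(col).group(1))
            records.append(BloomRecord(genotype, century * 100 + yy, int(row[col])))
    records.sort(key=lambda r: (r.genotype, r.year))
    return records


def records_to_frame(records: list[BloomRecord]) -> pd.DataFrame:
    """Long-format frame with the canonical Genotype / Year / pheno columns."""
    return pd.DataFrame(
        [(r.genotype, r.year, r.pheno) for r in records],
        columns=["Genotype", "Year", "pheno"],
    )


def long_to_wide(records: list[BloomRecord], century: int = 20) -> pd.DataFrame:
    """Inverse of :func:`wide_to_long` on valid cells (BDyy columns, year order)."""
    frame = records_to_frame(records)
    if frame.empty:
        return pd.DataFrame(columns=["Genotype"])
    frame["col"] = "BD" + (frame["Year"] - century * 100).astype(int).astype(str).str.zfill(2)
    wide = frame.pivot(index="Genotype", columns="col", values="pheno")
    wide = wide[sorted(wide.columns)].astype("Int64").reset_index()
    wide.columns.name = None
    return wide


def parse_genotype_id(raw: str) -> GenotypeId:
    """Split a '<group1>_<group2>' genotype code into its numeric parts."""
    match = _GENOTYPE_ID.match(str(raw))
    if not match:
        raise IdentifierError(
            f"genotype identifier {raw!r} does not match the '<int>_<int>' pattern"
        )
    return GenotypeId(str(raw), int(match.group(1)), int(match.group(2)))


def split_by_genotype(
    records: list[BloomRecord],
    out_dir: str | Path | None = None,
    file_id: str = "genotype",
) -> dict[str, list[BloomRecord]]:
    """Partition records by genotype, optionally exporting one CSV per group.

    Export files are named ``<file_id>_<group1>_<group2>.csv`` after the
    numeric parts of the genotype code.
    """
    groups: dict[str, list[BloomRecord]] = {}
    for rec in records:
        groups.setdefault(rec.genotype, []).append(rec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for genotype, recs in groups.items():
            gid = parse_genotype_id(genotype)
            records_to_frame(recs).to_csv(
                out_dir / f"{file_id}_{gid.group1}_{gid.group2}.csv", index=False
            )
    return groups
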