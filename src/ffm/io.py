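"""Reading and writing the pipeline's tabular formats (CSV/XLSX measurement
tables, FSP matrices, species summaries)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FSPMatrix
from .schema import DEFAULT_SCHEMA, TraitSchema
from .trait_data import SpecimenRecord

logger = logging.getLogger(__name__)

#: accepted (lower-cased) headers for the non-trait columns
_ID_HEADERS = ("specimen_id", "specimen", "id")
_SPECIES_HEADERS = ("species",)
_STATUS_HEADERS = ("status", "origin")
_SL_HEADERS = ("sl", "standard_length", "standard length (mm)", "standard length")


@dataclass
class LoadReport:
    """Bookkeeping for one measurement-table load."""

    rows_read: int = 0
    records: int = 0
    invalid_rows: list[str] = field(default_factory=list)
    missing_per_trait: dict[str, int] = field(default_factory=dict)
    ignored_columns: list[str] = field(default_factory=list)


def _read_table(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet)
    return pd.read_csv(path)


def load_measurements(
    path: str | Path,
    schema: TraitSchema = DEFAULT_SCHEMA,
    aliases: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> list[SpecimenRecord]:
    """Load a specimen measurement table (CSV or XLSX) into records.

    Headers are matched case-insensitively against schema abbreviations;
    ``aliases`` maps nonstandard headers to abbreviations. Rows without a
    parseable SL or species are excluded (logged); unparseable trait cells
    become missing entries, to be handled by ``filter_complete``. A load
    report (row counts, missing cells per trait, ignored columns) is logged.

    Raises
    ------
    ValueError
        If the species or SL column is absent.
    """
    df = _read_table(path, sheet=sheet)
    report = LoadReport(rows_read=len(df))

    aliases = {k.lower(): v for k, v in (aliases or {}).items()}
    by_lower = {a.lower(): a for a in schema.abbreviations}

    col_role: dict[str, str] = {}  # original header -> role
    for col in df.columns:
        key = str(col).strip().lower()
        key = aliases.get(key, key)
        if key.lower() in by_lower:
            col_role[col] = by_lower[key.lower()]
        elif key in _SPECIES_HEADERS:
            col_role[col] = "@species"
        elif key in _SL_HEADERS:
            col_role[col] = "@sl"
        elif key in _STATUS_HEADERS:
            col_role[col] = "@status"
        elif key in _ID_HEADERS:
            col_role[col] = "@id"
        else:
            report.ignored_columns.append(str(col))
            logger.warning("load_measurements: ignoring unknown column %r", col)

    roles = set(col_role.values())
    if "@species" not in roles:
        raise ValueError("measurement table has no 'species' column")
    if "@sl" not in roles:
        raise ValueError("measurement table has no 'SL' (standard length) column")
    if "@status" not in roles:
        logger.warning("load_measurements: no 'status' column; defaulting to 'native'")

    inv = {role: col for col, role in col_role.items()}
    records: list[SpecimenRecord] = []
    for i, row in df.iterrows():
        species = row[inv["@species"]]
        if pd.isna(species) or str(species).strip() == "":
            report.invalid_rows.append(f"row {i}: blank species")
            continue
        sl = pd.to_numeric(row[inv["@sl"]], errors="coerce")
        if pd.isna(sl) or sl <= 0:
            report.invalid_rows.append(f"row {i}: invalid SL {row[inv['@sl']]!r}")
            continue
        status = "native"
        if "@status" in inv and not pd.isna(row[inv["@status"]]):
            status = str(row[inv["@status"]]).strip().lower()
        sid = (
            str(row[inv["@id"]])
            if "@id" in inv and not pd.isna(row[inv["@id"]])
            else f"specimen_{i}"
        )
        traits: dict[str, float] = {}
        for col, role in col_role.items():
            if role.startswith("@"):
                continue
            v = pd.to_numeric(row[col], errors="coerce")
            if pd.isna(v):
                report.missing_per_trait[role] = report.missing_per_trait.get(role, 0) + 1
            else:
                traits[role] = float(v)
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species=str(species).strip(),
                status=status,
                standard_length=float(sl),
                raw_traits=traits,
            )
        )

    report.records = len(records)
    if report.rows_read == 0:
        logger.warning("load_measurements: %s contains no data rows", path)
    for msg in report.invalid_rows:
        logger.warning("load_measurements: excluded %s", msg)
    logger.info(
        "load_measurements: %d rows -> %d records; missing cells per trait: %s",
        report.rows_read,
        report.records,
        report.missing_per_trait or "none",
    )
    return records


def read_fsp(
    path: str | Path,
    schema: TraitSchema | None = None,
    optimum_traits: frozenset[str] | set[str] | None = None,
) -> FSPMatrix:
    """Read a food-specialist-profile matrix from CSV.

    Layout: first column = food type, remaining columns = trait abbreviations,
    integer cells in -2..+2. Optimum-type traits are declared via
    ``optimum_traits`` (sidecar config), defaulting to none.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "food_type"
    effects = df.astype(int)
    if schema is not None:
        missing = set(schema.abbreviations) - set(effects.columns)
        extra = set(effects.columns) - set(schema.abbreviations)
        if missing or extra:
            raise ValueError(
                f"FSP traits do not match schema (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
        effects = effects.reindex(columns=schema.abbreviations)
    return FSPMatrix(effects=effects, optimum_traits=frozenset(optimum_traits or ()))


def write_fsp(fsp: FSPMatrix, path: str | Path) -> None:
    fsp.effects.to_csv(path)


def write_species_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a species summary CSV with the conventional display columns."""
    out = summary.copy()
    out["standard_length_range_mm"] = [
        f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(out["sl_min"], out["sl_max"])
    ]
    cols = ["species", "status", "n", "standard_length_range_mm", "sl_mean", "sl_sd"]
    out[cols].to_csv(path, index=False)


def write_trophic_profiles(tp: pd.DataFrame, species: pd.Series, path: str | Path) -> None:
    out = tp.copy()
    out.insert(0, "species", species.reindex(tp.index).to_numpy())
    out.to_csv(path)


def write_records_csv(records: list[SpecimenRecord], schema: TraitSchema, path: str | Path) -> None:
    """Write specimen records as a measurement CSV (the load_measurements layout)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "status": r.status,
            "SL": r.standard_length,
        }
        for a in schema.abbreviations:
            row[a] = r.raw_traits.get(a, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
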