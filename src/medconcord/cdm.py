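"""Common-data-model-shaped tables: typed records, CSV I/O, and cohort validation.

The analysis operates on five flat tables mirroring the PCORnet CDM v3.0
surface that a prescribing/dispensing concordance study touches:

``prescribing``   provider medication orders from the EHR (RxNorm-coded)
``dispensing``    outpatient pharmacy fills (NDC-coded)
``encounter``     visits with an encounter type (AV/ED/IP/OT/UN)
``diagnosis``     same-day infection diagnoses, pre-tiered 1/2/3/other
``demographic``   one row per patient: covariates and institution

Dates are integer day offsets from each patient's cohort origin rather than
calendar dates; the matching logic only ever needs relative days.  In-memory
the tables are pandas DataFrames with normalized lower-case column names;
the dataclasses below define the per-row contract and are convertible
to/from frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

__all__ = [
    "ENC_TYPES",
    "TIERS",
    "SchemaError",
    "MedRecord",
    "EncounterRecord",
    "DiagnosisRecord",
    "PatientRecord",
    "CohortTables",
    "ValidationReport",
    "read_table",
    "write_table",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: Closed set of encounter types (ambulatory, emergency, inpatient, other, unknown).
ENC_TYPES = ("AV", "ED", "IP", "OT", "UN")

#: Infection-diagnosis tiers: 1 = antibiotics nearly always indicated,
#: 2 = discretionary, 3 = rarely indicated; "other_missing" = no same-day
#: infection diagnosis or an unclassified one.
TIERS = ("1", "2", "3", "other_missing")

TABLE_NAMES = ("prescribing", "dispensing", "encounter", "diagnosis", "demographic")


class SchemaError(ValueError):
    """A required column is absent or a table fails its schema contract."""


@dataclass(frozen=True)
class MedRecord:
    """One prescribing or dispensing event — the atom of the analysis."""

    record_id: str
    patid: str
    institution_id: str
    day: int
    code: str
    raw_name: str = ""
    stream: str = "prescribing"  # "prescribing" | "dispensing"

    def __post_init__(self):
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if not self.code:
            raise ValueError("code must be non-empty")
        if self.stream not in ("prescribing", "dispensing"):
            raise ValueError(f"unknown stream {self.stream!r}")


@dataclass(frozen=True)
class EncounterRecord:
    patid: str
    day: int
    enc_type: str = "UN"

    def __post_init__(self):
        if self.enc_type not in ENC_TYPES:
            raise ValueError(f"enc_type must be one of {ENC_TYPES}")


@dataclass(frozen=True)
class DiagnosisRecord:
    patid: str
    day: int
    tier: str = "other_missing"

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}")


@dataclass(frozen=True)
class PatientRecord:
    """One cohort member with the covariates the missingness models use."""

    patid: str
    institution_id: str
    institution_type: str  # "cIDS" | "non_cIDS"
    sex: str  # "male" | "female"
    race: str  # Asian / Black / White / Other / Unknown
    hispanic: str  # "yes" | "no_unknown"
    chronic_condition: bool
    asthma: bool
    preterm: bool
    encounter_count: int

    def __post_init__(self):
        if self.encounter_count < 0:
            raise ValueError("encounter_count must be >= 0")
        if self.institution_type not in ("cIDS", "non_cIDS"):
            raise ValueError("institution_type must be cIDS or non_cIDS")


# CDM v3.0 column names (and documented synonyms) -> normalized names, per table.
_DEFAULT_SYNONYMS: dict[str, dict[str, str]] = {
    "prescribing": {
        "RECORD_ID": "record_id",
        "PRESCRIBINGID": "record_id",
        "PATID": "patid",
        "INSTITUTION_ID": "institution_id",
        "SITEID": "institution_id",
        "DAY": "day",
        "RX_ORDER_DAY": "day",
        "RXNORM_CUI": "code",
        "RAW_RX_MED_NAME": "raw_name",
    },
    "dispensing": {
        "RECORD_ID": "record_id",
        "DISPENSINGID": "record_id",
        "PATID": "patid",
        "INSTITUTION_ID": "institution_id",
        "SITEID": "institution_id",
        "DAY": "day",
        "DISPENSE_DAY": "day",
        "NDC": "code",
    },
    "encounter": {
        "PATID": "patid",
        "DAY": "day",
        "ADMIT_DAY": "day",
        "ENC_TYPE": "enc_type",
    },
    "diagnosis": {
        "PATID": "patid",
        "DAY": "day",
        "ADMIT_DAY": "day",
        "TIER": "tier",
        "DX_TIER": "tier",
    },
    "demographic": {
        "PATID": "patid",
        "INSTITUTION_ID": "institution_id",
        "SITEID": "institution_id",
        "INSTITUTION_TYPE": "institution_type",
        "SEX": "sex",
        "RACE": "race",
        "HISPANIC": "hispanic",
        "CHRONIC_CONDITION": "chronic_condition",
        "ASTHMA": "asthma",
        "PRETERM": "preterm",
        "ENCOUNTER_COUNT": "encounter_count",
    },
}

_REQUIRED: dict[str, tuple[str, ...]] = {
    "prescribing": ("patid", "day", "code"),
    "dispensing": ("patid", "day", "code"),
    "encounter": ("patid", "day", "enc_type"),
    "diagnosis": ("patid", "day", "tier"),
    "demographic": ("patid", "institution_id", "institution_type", "sex", "race"),
}

_STREAM_OF = {"prescribing": "prescribing", "dispensing": "dispensing"}


def _normalize_columns(df: pd.DataFrame, schema: str, synonyms=None) -> pd.DataFrame:
    syn = dict(_DEFAULT_SYNONYMS[schema])
    if synonyms:
        syn.update({k.upper(): v for k, v in synonyms.items()})
    rename = {}
    for col in df.columns:
        key = col.strip().upper()
        rename[col] = syn.get(key, col.strip().lower())
    return df.rename(columns=rename)


def read_table(path, schema: str, *, synonyms: dict | None = None,
               on_bad_rows: str = "error") -> pd.DataFrame:
    """Read one CDM-shaped CSV into a validated, normalized DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row using CDM column names (PATID, DAY,
        RXNORM_CUI, NDC, ENC_TYPE, ...) or configured synonyms.
    schema
        One of ``prescribing``/``dispensing``/``encounter``/``diagnosis``/
        ``demographic``.
    synonyms
        Extra column-name mappings (source name -> normalized name) merged
        over the CDM v3.0 defaults.
    on_bad_rows
        ``"error"`` raises listing offending row numbers; ``"drop"`` removes
        them with a warning.  Rows are bad when ``day`` is not a
        non-negative integer or a required field is empty.

    Returns a DataFrame whose columns follow the normalized (lower-case)
    naming; medication tables gain a ``stream`` column and an auto-generated
    ``record_id`` when the file has none.  Unknown encounter types map to
    ``UN`` with a warning.
    """
    if schema not in TABLE_NAMES:
        raise ValueError(f"unknown schema {schema!r}; expected one of {TABLE_NAMES}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _normalize_columns(df, schema, synonyms)

    missing = [c for c in _REQUIRED[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema} table {path}: missing required column(s) {', '.join(missing)}"
        )
    return _coerce_table(df, schema, on_bad_rows=on_bad_rows)


def _coerce_table(df: pd.DataFrame, schema: str, *, on_bad_rows="error") -> pd.DataFrame:
    df = df.copy()
    bad_rows: list[int] = []

    if "day" in _REQUIRED[schema] or "day" in df.columns and schema != "demographic":
        day = pd.to_numeric(df["day"], errors="coerce")
        bad = day.isna() | (day % 1 != 0) | (day < 0)
        bad_rows.extend(df.index[bad].tolist())
        df["day"] = day

    for col in ("patid", "code"):
        if col in _REQUIRED[schema]:
            empty = df[col].astype(str).str.len() == 0
            bad_rows.extend(df.index[empty].tolist())

    if bad_rows:
        rows = sorted(set(bad_rows))
        if on_bad_rows == "error":
            raise ValueError(
                f"{schema} table: {len(rows)} invalid row(s) at index {rows[:20]}"
                f"{'...' if len(rows) > 20 else ''}"
            )
        warnings.warn(f"{schema} table: dropped {len(rows)} invalid row(s)",
                      stacklevel=2)
        df = df.drop(index=rows)

    if "day" in df.columns and schema != "demographic":
        df["day"] = df["day"].astype(int)

    if schema in _STREAM_OF:
        df["stream"] = _STREAM_OF[schema]
        if "record_id" not in df.columns or (df["record_id"] == "").all():
            prefix = "rx" if schema == "prescribing" else "dp"
            df["record_id"] = [f"{prefix}{i:08d}" for i in range(len(df))]
        if "raw_name" not in df.columns:
            df["raw_name"] = ""
        if "institution_id" not in df.columns:
            df["institution_id"] = ""

    if schema == "encounter":
        unknown = ~df["enc_type"].isin(ENC_TYPES)
        if unknown.any():
            warnings.warn(
                f"encounter table: {int(unknown.sum())} unknown ENC_TYPE value(s) "
                "mapped to UN", stacklevel=2)
            df.loc[unknown, "enc_type"] = "UN"

    if schema == "diagnosis":
        df["tier"] = df["tier"].astype(str)
        df.loc[~df["tier"].isin(TIERS), "tier"] = "other_missing"

    if schema == "demographic":
        for col in ("chronic_condition", "asthma", "preterm"):
            if col in df.columns:
                df[col] = df[col].astype(str).str.lower().isin(("1", "true", "yes", "y"))
        if "encounter_count" in df.columns:
            df["encounter_count"] = pd.to_numeric(
                df["encounter_count"], errors="coerce").fillna(0).astype(int)

    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a normalized table back to CSV (inverse of :func:`read_table`)."""
    out = df.copy()
    rename = {v: k for k, v in _DEFAULT_SYNONYMS[schema].items()}
    # prefer the primary CDM name when several synonyms share a target
    primary = {
        "record_id": "RECORD_ID", "patid": "PATID", "day": "DAY",
        "institution_id": "INSTITUTION_ID",
        "code": "RXNORM_CUI" if schema == "prescribing" else "NDC",
        "raw_name": "RAW_RX_MED_NAME", "enc_type": "ENC_TYPE", "tier": "TIER",
    }
    rename.update({k: v for k, v in primary.items() if k in out.columns})
    out = out.drop(columns=[c for c in ("stream",) if c in out.columns])
    out = out.rename(columns={c: rename.get(c, c.upper()) for c in out.columns})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


@dataclass
class CohortTables:
    """The five tables of one cohort extract."""

    prescribing: pd.DataFrame
    dispensing: pd.DataFrame
    encounter: pd.DataFrame
    diagnosis: pd.DataFrame
    demographic: pd.DataFrame

    def __iter__(self):
        for name in TABLE_NAMES:
            yield name, getattr(self, name)


def read_cohort(directory, **kwargs) -> CohortTables:
    """Read ``prescribing.csv`` ... ``demographic.csv`` from a directory."""
    directory = Path(directory)
    return CohortTables(**{
        name: read_table(directory / f"{name}.csv", name, **kwargs)
        for name in TABLE_NAMES
    })


def write_cohort(tables: CohortTables, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables:
        write_table(df, directory / f"{name}.csv", name)


@dataclass
class ValidationReport:
    """Report-only data-quality summary of a cohort (no exceptions raised)."""

    orphan_records: dict[str, int] = field(default_factory=dict)
    duplicate_record_ids: dict[str, int] = field(default_factory=dict)
    day_range: dict[str, tuple[int, int]] = field(default_factory=dict)
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_cohort(tables: CohortTables) -> ValidationReport:
    """Cross-table consistency checks: orphan patids, duplicate record ids,
    per-table day ranges.  Mirrors a distributed network's basic curation
    pass; always returns a report, never raises."""
    report = ValidationReport()
    known = set(tables.demographic["patid"])
    for name, df in tables:
        if name == "demographic" or df.empty:
            continue
        orphans = int((~df["patid"].isin(known)).sum())
        if orphans:
            report.orphan_records[name] = orphans
            report.issues.append(f"{name}: {orphans} record(s) with unknown patid")
        if "record_id" in df.columns:
            dups = int(df["record_id"].duplicated().sum())
            if dups:
                report.duplicate_record_ids[name] = dups
                report.issues.append(f"{name}: {dups} duplicated record_id(s)")
        if "day" in df.columns:
            report.day_range[name] = (int(df["day"].min()), int(df["day"].max()))
    dup_pat = int(tables.demographic["patid"].duplicated().sum())
    if dup_pat:
        report.duplicate_record_ids["demographic"] = dup_pat
        report.issues.append(f"demographic: {dup_pat} duplicated patid(s)")
    # institution_type must be constant within institution_id
    by_inst = tables.demographic.groupby("institution_id")["institution_type"].nunique()
    mixed = by_inst[by_inst > 1]
    for inst in mixed.index:
        report.issues.append(f"demographic: institution {inst} has mixed institution_type")
    return report


def records_from_frame(df: pd.DataFrame, cls):
    """Materialize dataclass records from a normalized frame (row-level API)."""
    names = [f.name for f in fields(cls)]
    cols = [c for c in names if c in df.columns]
    return [cls(**{c: row[c] for c in cols}) for row in df[cols].to_dict("records")]
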