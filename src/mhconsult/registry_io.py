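"""Reading, validating and writing consultation-level registry extracts.

The file dialect is UTF-8 comma-delimited text with a header row,
ISO-8601 dates, and multi-code diagnosis cells joined with ``;``.
Diagnosis codes follow the ICPC-2 pattern (one letter, two digits) and are
case-normalized to uppercase on read.  Contact types are the eight
reimbursement categories used for GP billing (day/evening crossed with
in-person/e-consultation crossed with regular GP/out-of-hours service);
an unknown category is an error, never a silent pass-through.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ICPC2_PATTERN = re.compile(r"^[A-Z][0-9]{2}$")

#: The eight reimbursement contact categories for a GP consultation.
CONTACT_TYPES = (
    "gp_day",
    "gp_evening",
    "ooh_day",
    "ooh_evening",
    "gp_e_day",
    "gp_e_evening",
    "ooh_e_day",
    "ooh_e_evening",
)

GENDERS = ("female", "male")

#: ICPC-2 age window of the registry extract.
MIN_BIRTH_YEAR = 1900

CONSULTATION_COLUMNS = ("patient_id", "date", "diagnosis_codes", "contact_type")
POPULATION_COLUMNS = ("patient_id", "gender", "birth_year")
WEEKLY_COLUMNS = ("diagnosis", "stratum", "iso_year", "iso_week", "count")


class RegistrySchemaError(ValueError):
    """A file is structurally unusable (missing column, bad header)."""


class RegistryRowError(ValueError):
    """A single row failed validation; carries its 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Dialect:
    """Physical format options for the delimited-text registry files."""

    delimiter: str = ","
    code_separator: str = ";"
    encoding: str = "utf-8"


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class PatientRecord:
    """One person in the population table."""

    patient_id: str
    gender: str
    birth_year: int

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        current_year = dt.date.today().year
        if not (MIN_BIRTH_YEAR <= self.birth_year <= current_year):
            raise ValueError(
                f"birth_year {self.birth_year} outside [{MIN_BIRTH_YEAR}, {current_year}]"
            )


@dataclass(frozen=True)
class ConsultationRecord:
    """One reimbursed GP contact: patient, date, ICPC-2 codes, contact type."""

    patient_id: str
    date: dt.date
    diagnosis_codes: frozenset[str]
    contact_type: str

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.diagnosis_codes:
            raise ValueError("diagnosis_codes must be non-empty")
        for code in self.diagnosis_codes:
            if not ICPC2_PATTERN.match(code):
                raise ValueError(f"invalid ICPC-2 code {code!r}")
        if self.contact_type not in CONTACT_TYPES:
            raise ValueError(
                f"contact_type must be one of {CONTACT_TYPES}, got {self.contact_type!r}"
            )


@dataclass(frozen=True)
class CodeSet:
    """The ICPC-2 codes defining cohort inclusion and analysis.

    ``inclusion_codes`` define a pre-existing mental health problem: the five
    disorder codes plus the two symptom codes P03 (feeling depressed) and P01
    (feeling anxious), which may precede a later disorder diagnosis.
    ``analysis_codes`` are the disorder codes only; symptom-coded
    consultations never enter the analysed counts.
    """

    inclusion_codes: frozenset[str] = frozenset(
        {"P03", "P76", "P01", "P74", "P79", "P82", "P86"}
    )
    analysis_codes: frozenset[str] = frozenset({"P76", "P74", "P79", "P82", "P86"})
    display_names: Mapping[str, str] = field(
        default_factory=lambda: {
            "P01": "feeling anxious",
            "P03": "feeling depressed",
            "P74": "anxiety disorder",
            "P76": "depressive disorder",
            "P79": "phobia/OCD",
            "P82": "PTSD",
            "P86": "eating disorders",
        }
    )

    def __post_init__(self):
        object.__setattr__(self, "inclusion_codes", frozenset(self.inclusion_codes))
        object.__setattr__(self, "analysis_codes", frozenset(self.analysis_codes))
        if not self.analysis_codes <= self.inclusion_codes:
            raise ValueError("analysis_codes must be a subset of inclusion_codes")
        for code in self.inclusion_codes:
            if not ICPC2_PATTERN.match(code):
                raise ValueError(f"invalid ICPC-2 code {code!r}")


DEFAULT_CODES = CodeSet()


def normalize_codes(cell: str, dialect: Dialect = DEFAULT_DIALECT) -> frozenset[str]:
    """Split a multi-code cell, uppercase, validate, and return the code set."""
    parts = [p.strip().upper() for p in str(cell).split(dialect.code_separator)]
    codes = frozenset(p for p in parts if p)
    if not codes:
        raise ValueError(f"empty diagnosis-code cell {cell!r}")
    for code in codes:
        if not ICPC2_PATTERN.match(code):
            raise ValueError(f"invalid ICPC-2 code {code!r}")
    return codes


def codes_to_cell(codes: Iterable[str], dialect: Dialect = DEFAULT_DIALECT) -> str:
    return dialect.code_separator.join(sorted(codes))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegistrySchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_consultations_frame(
    path, dialect: Dialect = DEFAULT_DIALECT
) -> pd.DataFrame:
    """Read a consultations file into a validated DataFrame.

    Columns of the result: ``patient_id`` (str), ``date`` (datetime64),
    ``diagnosis_codes`` (canonical uppercase ``;``-joined sorted string),
    ``contact_type`` (str).  Row order is preserved.
    """
    df = pd.read_csv(
        path, sep=dialect.delimiter, encoding=dialect.encoding, dtype=str,
        skip_blank_lines=False,
    )
    _require_columns(df, CONSULTATION_COLUMNS, path)
    if df.empty:
        logger.warning("%s: no consultation rows", path)
        return df.assign(date=pd.to_datetime(df.get("date")))

    # data rows start at physical line 2 (header is line 1)
    lines = df.index.to_numpy() + 2

    if df[list(CONSULTATION_COLUMNS)].isna().any(axis=None):
        bad = df.index[df[list(CONSULTATION_COLUMNS)].isna().any(axis=1)][0]
        raise RegistryRowError("missing value", int(bad) + 2)

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        bad = int(dates.index[dates.isna()][0])
        raise RegistryRowError(f"unparseable date {df['date'][bad]!r}", int(lines[bad]))

    canonical = []
    for i, cell in enumerate(df["diagnosis_codes"]):
        try:
            canonical.append(codes_to_cell(normalize_codes(cell, dialect), dialect))
        except ValueError as exc:
            raise RegistryRowError(str(exc), int(lines[i])) from exc

    ct = df["contact_type"].str.strip()
    bad_ct = ~ct.isin(CONTACT_TYPES)
    if bad_ct.any():
        bad = int(ct.index[bad_ct][0])
        raise RegistryRowError(
            f"unknown contact_type {ct[bad]!r}", int(lines[bad])
        )

    empty_pid = df["patient_id"].str.len() == 0
    if empty_pid.any():
        raise RegistryRowError("empty patient_id", int(lines[int(df.index[empty_pid][0])]))

    return pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "date": dates.to_numpy(),
            "diagnosis_codes": canonical,
            "contact_type": ct.to_numpy(),
        }
    )


def read_consultations(
    path, dialect: Dialect = DEFAULT_DIALECT
) -> list[ConsultationRecord]:
    """Read a consultations file as a list of validated records."""
    return frame_to_records(read_consultations_frame(path, dialect), dialect)


def frame_to_records(
    frame: pd.DataFrame, dialect: Dialect = DEFAULT_DIALECT
) -> list[ConsultationRecord]:
    return [
        ConsultationRecord(
            patient_id=row.patient_id,
            date=row.date.date() if hasattr(row.date, "date") else row.date,
            diagnosis_codes=frozenset(row.diagnosis_codes.split(dialect.code_separator)),
            contact_type=row.contact_type,
        )
        for row in frame.itertuples(index=False)
    ]


def records_to_frame(
    records: Iterable[ConsultationRecord], dialect: Dialect = DEFAULT_DIALECT
) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "date": pd.to_datetime([r.date for r in records]),
            "diagnosis_codes": [codes_to_cell(r.diagnosis_codes, dialect) for r in records],
            "contact_type": [r.contact_type for r in records],
        }
    )


def as_consultation_frame(consultations, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Accept either a DataFrame or an iterable of ConsultationRecord."""
    if isinstance(consultations, pd.DataFrame):
        return consultations
    return records_to_frame(consultations, dialect)


def write_consultations(
    consultations, path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    frame = as_consultation_frame(consultations, dialect).copy()
    frame["date"] = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False, sep=dialect.delimiter, encoding=dialect.encoding)


def read_population_frame(path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a population table into a validated DataFrame."""
    df = pd.read_csv(path, sep=dialect.delimiter, encoding=dialect.encoding, dtype=str)
    _require_columns(df, POPULATION_COLUMNS, path)
    if df.empty:
        logger.warning("%s: empty population table", path)
        return df.assign(birth_year=pd.Series(dtype=int))
    dup = df["patient_id"].duplicated()
    if dup.any():
        ids = sorted(df.loc[dup, "patient_id"].unique())
        raise RegistrySchemaError(f"{path}: duplicate patient_id(s): {', '.join(ids)}")
    gender = df["gender"].str.strip().str.lower()
    bad = ~gender.isin(GENDERS)
    if bad.any():
        raise RegistryRowError(
            f"gender {df['gender'][int(df.index[bad][0])]!r} not in {GENDERS}",
            int(df.index[bad][0]) + 2,
        )
    try:
        birth_year = df["birth_year"].astype(int)
    except ValueError as exc:
        raise RegistryRowError(f"unparseable birth_year: {exc}", 0) from exc
    return pd.DataFrame(
        {"patient_id": df["patient_id"], "gender": gender, "birth_year": birth_year}
    )


def read_population(path, dialect: Dialect = DEFAULT_DIALECT) -> dict[str, PatientRecord]:
    """Read a population table as a map patient_id -> PatientRecord."""
    frame = read_population_frame(path, dialect)
    return {
        row.patient_id: PatientRecord(row.patient_id, row.gender, int(row.birth_year))
        for row in frame.itertuples(index=False)
    }


def as_population_frame(population, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    if isinstance(population, pd.DataFrame):
        return population
    records = population.values() if isinstance(population, Mapping) else list(population)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "gender": [r.gender for r in records],
            "birth_year": [r.birth_year for r in records],
        }
    )


def write_population(population, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    as_population_frame(population).to_csv(
        path, index=False, sep=dialect.delimiter, encoding=dialect.encoding
    )


def write_weekly_counts(series, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    """Write a WeeklyCountSeries to weekly_counts.csv (header always present)."""
    rows = pd.DataFrame(
        {
            "diagnosis": series.diagnosis,
            "stratum": str(series.stratum),
            "iso_year": [p[0] for p in series.points],
            "iso_week": [p[1] for p in series.points],
            "count": [p[2] for p in series.points],
        }
    )
    rows.to_csv(path, index=False, sep=dialect.delimiter, encoding=dialect.encoding)


def read_weekly_counts(path, dialect: Dialect = DEFAULT_DIALECT):
    """Read weekly_counts.csv back into a WeeklyCountSeries."""
    from .weekly import Stratifier, WeeklyCountSeries

    df = pd.read_csv(path, sep=dialect.delimiter, encoding=dialect.encoding)
    _require_columns(df, WEEKLY_COLUMNS, path)
    if df.empty:
        raise RegistrySchemaError(f"{path}: weekly-count file has no rows")
    diagnosis = df["diagnosis"].iloc[0]
    stratum = Stratifier.parse(str(df["stratum"].iloc[0]))
    points = [
        (int(r.iso_year), int(r.iso_week), int(r.count))
        for r in df.itertuples(index=False)
    ]
    return WeeklyCountSeries(diagnosis=diagnosis, stratum=stratum, points=points)
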