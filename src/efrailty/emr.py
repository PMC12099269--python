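"""CPCSSN-style flat-table input: reading, validation, windowing, eligibility.

The engine consumes four flat CSV tables as distributed by primary-care
sentinel networks — patients, encounter diagnoses (coded and free-text),
labs, and medications — into one in-memory cohort.  Rows violating a
table's invariant (no patient id, unparseable date, a diagnosis with
neither code nor text, ...) are dropped but always *counted and logged*,
never silently discarded, so row attrition stays auditable.

The observation window models the study-style extraction range: records are
filtered to [start_date, end_date] (both inclusive) and age eligibility is
assessed at an index date, defaulting to the window end.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Required headers per table; the reader fails hard on a missing column.
TABLE_COLUMNS: dict[str, list[str]] = {
    "patient": ["patient_id", "birth_date", "sex"],
    "diagnosis": ["patient_id", "encounter_date", "code_system", "code", "text"],
    "lab": ["patient_id", "date", "loinc_code", "value", "unit"],
    "medication": ["patient_id", "prescribed_date", "atc_code", "drug_name"],
}

DATE_COLUMN = {
    "patient": "birth_date",
    "diagnosis": "encounter_date",
    "lab": "date",
    "medication": "prescribed_date",
}

# Default extraction range: five years of records, age assessed at the end.
DEFAULT_WINDOW_START = dt.date(2017, 7, 1)
DEFAULT_WINDOW_END = dt.date(2022, 6, 30)


class CohortError(ValueError):
    """Raised when an input table cannot be read at all (file/columns)."""


@dataclass(frozen=True)
class ObservationWindow:
    """Record-extraction range plus the index date used as the age reference."""

    start_date: dt.date = DEFAULT_WINDOW_START
    end_date: dt.date = DEFAULT_WINDOW_END
    index_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("window start_date after end_date")
        if self.index_date is None:
            object.__setattr__(self, "index_date", self.end_date)
        if self.index_date < self.start_date:
            raise ValueError("index_date before window start")

    def contains(self, when: dt.date) -> bool:
        return self.start_date <= when <= self.end_date


@dataclass
class EmrCohort:
    """The four tables in a common typed form, plus row-rejection counts.

    Date columns hold ``datetime.date`` objects; every other column is a
    plain string ("" for missing).  ``rejections`` maps table name to the
    number of rows dropped for invariant violations.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    rejections: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return {
            "patient": self.patients,
            "diagnosis": self.diagnoses,
            "lab": self.labs,
            "medication": self.medications,
        }[name]


def _read_table(name: str, path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"{name} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required column(s) {missing} in {name} table")
    return df[TABLE_COLUMNS[name]]


def _clean_table(name: str, df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the table invariant; return (kept rows, n rejected)."""
    n0 = len(df)
    df = df.copy()
    for col in df.columns:
        df[col] = df[col].astype(str).str.strip()
    keep = df["patient_id"] != ""
    date_col = DATE_COLUMN[name]
    parsed = pd.to_datetime(df[date_col], format="%Y-%m-%d", errors="coerce")
    keep &= parsed.notna()
    if name == "diagnosis":
        keep &= (df["code"] != "") | (df["text"] != "")
    elif name == "lab":
        keep &= df["loinc_code"] != ""
    elif name == "medication":
        keep &= (df["atc_code"] != "") | (df["drug_name"] != "")
    df = df.loc[keep].reset_index(drop=True)
    df[date_col] = parsed.loc[keep].dt.date.to_numpy(dtype=object)
    n_rejected = n0 - len(df)
    if n_rejected:
        logger.warning("%s table: rejected %d of %d rows (invariant violations)", name, n_rejected, n0)
    return df, n_rejected


def read_cohort(paths: dict[str, str | Path]) -> EmrCohort:
    """Read the four CSV tables into a typed cohort.

    ``paths`` maps table names (patient, diagnosis, lab, medication) to CSV
    files with the documented headers and ISO-8601 dates.  A missing file or
    column is a hard :class:`CohortError`; rows that fail a row-level
    invariant are dropped, counted in ``cohort.rejections`` and logged.
    """
    missing = [t for t in TABLE_COLUMNS if t not in paths]
    if missing:
        raise CohortError(f"missing table path(s): {missing}")
    tables: dict[str, pd.DataFrame] = {}
    rejections: dict[str, int] = {}
    for name in TABLE_COLUMNS:
        raw = _read_table(name, paths[name])
        tables[name], rejections[name] = _clean_table(name, raw)
        logger.info("%s table: %d rows read, %d kept", name, len(raw), len(tables[name]))
    dup = tables["patient"]["patient_id"].duplicated()
    if dup.any():
        raise CohortError(
            f"duplicate patient_id(s) in patient table: "
            f"{sorted(tables['patient'].loc[dup, 'patient_id'].unique())}"
        )
    return EmrCohort(
        patients=tables["patient"],
        diagnoses=tables["diagnosis"],
        labs=tables["lab"],
        medications=tables["medication"],
        rejections=rejections,
    )


def write_cohort(cohort: EmrCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort back to the four CSVs (round-trips retained rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLE_COLUMNS:
        df = cohort.table(name).copy()
        df[DATE_COLUMN[name]] = df[DATE_COLUMN[name]].map(lambda d: d.isoformat())
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths


def age_at(birth_date: dt.date, index_date: dt.date) -> int:
    """Age in completed years at the index date (birthday on the day counts)."""
    had_birthday = (index_date.month, index_date.day) >= (birth_date.month, birth_date.day)
    return index_date.year - birth_date.year - (0 if had_birthday else 1)


def eligible_patients(
    cohort: EmrCohort, window: ObservationWindow, min_age: int = 65
) -> set[str]:
    """Patients aged ``min_age`` or older (completed years) at the index date.

    A patient with an unparseable or future birth date was already rejected
    or is excluded here with a warning — never an error.
    """
    eligible: set[str] = set()
    for row in cohort.patients.itertuples(index=False):
        birth = row.birth_date
        if not isinstance(birth, dt.date):
            logger.warning("patient %s: missing birth_date, excluded", row.patient_id)
            continue
        if birth > window.index_date:
            logger.warning("patient %s: birth_date after index date, excluded", row.patient_id)
            continue
        if age_at(birth, window.index_date) >= min_age:
            eligible.add(row.patient_id)
    return eligible


def window_records(df: pd.DataFrame, date_col: str, window: ObservationWindow) -> pd.DataFrame:
    """Pure filter of a record table to the observation window (inclusive)."""
    if df.empty:
        return df
    mask = df[date_col].map(window.contains)
    return df.loc[mask]
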