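"""Patient-level domain model and cohort CSV input/output.

A :class:`PatientRecord` holds one admission for upper gastrointestinal
bleeding: demographics, vitals, laboratory values, bleeding presentation,
comorbidity codes, and the binary in-hospital-death outcome.  Every score
calculator in the package takes a ``PatientRecord`` and nothing else.

Missing-data policy is "complete case per score": any clinical field may
be absent (``None``) and each score is computed only when all of its own
inputs are present.  Records that violate hard physiological constraints
(age below 16, non-positive labs) are rejected at construction.

The on-disk format is a plain comma-separated, UTF-8, dot-decimal CSV
with lowercase ``snake_case`` enum values and semicolon-separated
comorbidity codes; see ``docs/column_dictionary.md`` for the full column
dictionary.
"""

from __future__ import annotations

import csv
import enum
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

__all__ = [
    "Sex",
    "Hematemesis",
    "GeneralCondition",
    "ComorbiditySeverity",
    "Ascites",
    "Encephalopathy",
    "CovidStatus",
    "Period",
    "EtiologyGroup",
    "KNOWN_COMORBIDITIES",
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "cohort_from_dataframe",
    "cohort_to_dataframe",
    "COLUMNS",
]


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Hematemesis(str, enum.Enum):
    none = "none"
    coffee_ground = "coffee_ground"
    red_blood = "red_blood"


class GeneralCondition(str, enum.Enum):
    poor = "poor"
    intermediate = "intermediate"
    good = "good"


class ComorbiditySeverity(str, enum.Enum):
    none = "none"
    chronic = "chronic"
    acute = "acute"


class Ascites(str, enum.Enum):
    none = "none"
    mild = "mild"
    moderate_severe = "moderate_severe"


class Encephalopathy(str, enum.Enum):
    none = "none"
    grade_1_2 = "grade_1_2"
    grade_3_4 = "grade_3_4"


class CovidStatus(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    untested = "untested"
    prepandemic = "prepandemic"


class Period(str, enum.Enum):
    prepandemic = "prepandemic"
    pandemic = "pandemic"


class EtiologyGroup(str, enum.Enum):
    """Bleeding etiology stratum used by the group-level analytics."""

    nonvariceal = "nonvariceal"
    variceal = "variceal"
    no_endoscopy = "no_endoscopy"


#: The 19 conditions of the original (1987) Charlson index, plus the
#: score-specific codes used by Rockall / Glasgow-Blatchford / INBS
#: (cardiac failure, ischemic heart disease, renal failure, cirrhosis,
#: disseminated malignancy).
CHARLSON_CODES = frozenset(
    {
        "myocardial_infarction",
        "congestive_heart_failure",
        "peripheral_vascular_disease",
        "cerebrovascular_disease",
        "dementia",
        "chronic_pulmonary_disease",
        "connective_tissue_disease",
        "peptic_ulcer_disease",
        "mild_liver_disease",
        "diabetes",
        "hemiplegia",
        "moderate_severe_renal_disease",
        "diabetes_with_end_organ_damage",
        "any_tumor",
        "leukemia",
        "lymphoma",
        "moderate_severe_liver_disease",
        "metastatic_solid_tumor",
        "aids",
    }
)

KNOWN_COMORBIDITIES = CHARLSON_CODES | {
    "cardiac_failure",
    "ischemic_heart_disease",
    "renal_failure",
    "liver_disease_cirrhosis",
    "disseminated_malignancy",
}

_POSITIVE_FIELDS = (
    "sbp",
    "heart_rate",
    "hemoglobin",
    "urea",
    "creatinine",
    "albumin",
    "inr",
    "bilirubin",
)


class PatientRecord(BaseModel):
    """One patient admission; the sole input to every score calculator."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    outcome_death: bool
    age: Optional[int] = None
    sex: Optional[Sex] = None
    sbp: Optional[float] = None
    heart_rate: Optional[float] = None
    hemoglobin: Optional[float] = None
    urea: Optional[float] = None
    creatinine: Optional[float] = None
    albumin: Optional[float] = None
    inr: Optional[float] = None
    bilirubin: Optional[float] = None
    syncope: Optional[bool] = None
    melena: Optional[bool] = None
    hematochezia: Optional[bool] = None
    hematemesis: Optional[Hematemesis] = None
    altered_mental_status: Optional[bool] = None
    general_condition: Optional[GeneralCondition] = None
    asa_class: Optional[int] = None
    antiplatelet: Optional[bool] = None
    anticoagulant: Optional[bool] = None
    nsaid: Optional[bool] = None
    comorbidities: Optional[frozenset[str]] = None
    comorbidity_count: Optional[int] = None
    comorbidity_severity: Optional[ComorbiditySeverity] = None
    ascites: Optional[Ascites] = None
    encephalopathy: Optional[Encephalopathy] = None
    covid_status: Optional[CovidStatus] = None
    period: Optional[Period] = None
    etiology_group: Optional[EtiologyGroup] = None

    @field_validator("age")
    @classmethod
    def _age_adult(cls, v):
        if v is not None and v < 16:
            raise ValueError(f"age must be >= 16 (got {v}); patients below 16 are excluded")
        return v

    @field_validator("asa_class")
    @classmethod
    def _asa_range(cls, v):
        if v is not None and not 1 <= v <= 5:
            raise ValueError(f"asa_class must be in 1..5, got {v}")
        return v

    @field_validator("comorbidity_count")
    @classmethod
    def _count_nonneg(cls, v):
        if v is not None and v < 0:
            raise ValueError("comorbidity_count must be non-negative")
        return v

    @field_validator("comorbidities")
    @classmethod
    def _known_codes(cls, v):
        if v is None:
            return v
        unknown = set(v) - KNOWN_COMORBIDITIES
        if unknown:
            raise ValueError(f"unknown comorbidity codes: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _physiology_and_period(self):
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.period == Period.prepandemic and self.covid_status not in (
            None,
            CovidStatus.prepandemic,
        ):
            raise ValueError(
                "covid_status must be 'prepandemic' for pre-pandemic admissions"
            )
        return self

    def has_comorbidity(self, *codes: str) -> bool:
        if self.comorbidities is None:
            return False
        return any(c in self.comorbidities for c in codes)


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of validated patient records."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        if not self.records:
            raise ValueError("cohort must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "Cohort":
        kept = tuple(r for r in self.records if predicate(r))
        if not kept:
            raise ValueError("subset is empty")
        return Cohort(records=kept, provenance=self.provenance + "|subset")


class CohortSchemaError(ValueError):
    """The CSV header does not match the column dictionary."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; carries (row_number, message) pairs."""

    def __init__(self, failures: list[tuple[int, str]]):
        self.failures = failures
        lines = "; ".join(f"row {n}: {msg}" for n, msg in failures[:10])
        more = "" if len(failures) <= 10 else f" (+{len(failures) - 10} more)"
        super().__init__(f"{len(failures)} invalid row(s): {lines}{more}")


#: Canonical CSV column order.
COLUMNS = [
    "id",
    "age",
    "sex",
    "sbp",
    "heart_rate",
    "hemoglobin",
    "urea",
    "creatinine",
    "albumin",
    "inr",
    "bilirubin",
    "syncope",
    "melena",
    "hematochezia",
    "hematemesis",
    "altered_mental_status",
    "general_condition",
    "asa_class",
    "antiplatelet",
    "anticoagulant",
    "nsaid",
    "comorbidities",
    "comorbidity_count",
    "comorbidity_severity",
    "ascites",
    "encephalopathy",
    "covid_status",
    "period",
    "etiology_group",
    "outcome_death",
]

_INT_COLS = {"age", "asa_class", "comorbidity_count"}
_FLOAT_COLS = {
    "sbp",
    "heart_rate",
    "hemoglobin",
    "urea",
    "creatinine",
    "albumin",
    "inr",
    "bilirubin",
}
_BOOL_COLS = {
    "syncope",
    "melena",
    "hematochezia",
    "altered_mental_status",
    "antiplatelet",
    "anticoagulant",
    "nsaid",
    "outcome_death",
}
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_cell(col: str, raw: str):
    raw = raw.strip()
    if raw == "":
        # an empty comorbidity cell means "none recorded" (empty set);
        # any other empty cell means the value is missing
        return frozenset() if col == "comorbidities" else None
    if col in _INT_COLS:
        return int(raw)
    if col in _FLOAT_COLS:
        return float(raw)
    if col in _BOOL_COLS:
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"cannot parse boolean {raw!r} for column {col!r}")
    if col == "comorbidities":
        return frozenset(p for p in raw.split(";") if p)
    return raw


def _format_cell(col: str, value) -> str:
    if value is None:
        return ""
    if col in _BOOL_COLS:
        return "1" if value else "0"
    if col == "comorbidities":
        return ";".join(sorted(value))
    if isinstance(value, enum.Enum):
        return value.value
    if col in _FLOAT_COLS:
        return format(float(value), "g")
    return str(value)


def record_from_row(row: dict[str, str]) -> PatientRecord:
    """Build a validated PatientRecord from a dict of raw CSV strings."""
    data = {}
    for col in COLUMNS:
        parsed = _parse_cell(col, row.get(col, ""))
        if parsed is not None:
            data[col] = parsed
    return PatientRecord(**data)


def read_cohort(path: str | Path, dialect: str = "excel") -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`CohortSchemaError` if mandatory columns are missing
    and :class:`CohortValidationError` listing every failing row (1-based
    data row numbers) if any record is invalid.  Rows are never silently
    dropped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise CohortSchemaError(f"missing mandatory column(s): {missing}")
        records: list[PatientRecord] = []
        failures: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(record_from_row(row))
            except (ValueError, ValidationError) as exc:
                failures.append((i, _short_error(exc)))
    if failures:
        raise CohortValidationError(failures)
    return Cohort(records=tuple(records), provenance=str(path))


def _short_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "record"
        return f"{loc}: {first['msg']}"
    return str(exc)


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = "excel") -> None:
    """Write a cohort to CSV in the canonical column dictionary order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, dialect=dialect)
        writer.writerow(COLUMNS)
        for rec in cohort:
            writer.writerow(
                [_format_cell(col, getattr(rec, col)) for col in COLUMNS]
            )


def cohort_to_dataframe(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame of raw CSV-format strings (one column per field)."""
    rows = [
        {col: _format_cell(col, getattr(rec, col)) for col in COLUMNS}
        for rec in cohort
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def cohort_from_dataframe(df: pd.DataFrame, provenance: str = "dataframe") -> Cohort:
    """Validate a DataFrame of raw string cells into a Cohort."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {missing}")
    records: list[PatientRecord] = []
    failures: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                record_from_row({c: str(v) for c, v in zip(df.columns, row)})
            )
        except (ValueError, ValidationError) as exc:
            failures.append((i, _short_error(exc)))
    if failures:
        raise CohortValidationError(failures)
    return Cohort(records=tuple(records), provenance=provenance)


def config_digest(payload: str) -> str:
    """Short stable digest used to tag generated cohorts' provenance."""
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
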