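"""Canonical in-memory EMR data model.

The analysis operates on six linked tables held as pandas DataFrames:
patients, GPs, encounters, prescriptions, laboratory results, and
vitals/biometrics. All dates are day-resolution ``datetime64[ns]``; ages are
year-resolution (only birth years are modelled, as in anonymised EMR
exports). Laboratory values are stored in one canonical unit per analyte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

GENDERS_PATIENT = ("female", "male", "other")
GENDERS_GP = ("female", "male", "unknown")

#: canonical storage unit per supported analyte
CANONICAL_UNITS: dict[str, str] = {
    "serum_creatinine": "umol/L",
    "egfr": "mL/min/1.73m2",
    "acr": "mg/mmol",
    "uac": "mg/L",
    "hemoglobin": "g/L",
    "sodium": "mmol/L",
    "potassium": "mmol/L",
    "urea": "mmol/L",
    "alkaline_phosphatase": "U/L",
    "calcium": "mmol/L",
    "phosphate": "mmol/L",
    "parathyroid_hormone": "ng/L",
    "hba1c": "%",
    "ldl": "mmol/L",
    "total_cholesterol": "mmol/L",
}

#: multiplicative conversions (analyte, source unit) -> canonical unit
UNIT_CONVERSIONS: dict[tuple[str, str], float] = {
    ("serum_creatinine", "mg/dL"): 88.42,
    ("acr", "mg/g"): 1.0 / 8.84,
    ("hemoglobin", "g/dL"): 10.0,
    ("calcium", "mg/dL"): 0.2495,
    ("phosphate", "mg/dL"): 0.3229,
    ("urea", "mg/dL"): 0.1665,
}

ATC_PATTERN = re.compile(r"^[A-V]\d\d[A-Z]{0,2}\d{0,2}$")
ICPC2_PATTERN = re.compile(r"^[A-Z]\d\d$")

#: required columns per table (canonical names)
TABLE_SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "gp_id", "gender", "birth_year"],
    "gps": ["gp_id", "gender", "birth_year", "urban_location"],
    "encounters": ["patient_id", "date", "icpc2_code"],
    "prescriptions": ["patient_id", "date", "atc_code", "end_date"],
    "labs": ["patient_id", "date", "analyte", "value", "unit"],
    "vitals": [
        "patient_id",
        "date",
        "systolic_bp",
        "diastolic_bp",
        "weight",
        "height",
        "bmi",
    ],
}

EVENT_TABLES = ("encounters", "prescriptions", "labs", "vitals")


class ValidationError(ValueError):
    """Raised when a dataset violates the data-model contract."""


@dataclass
class EmrDataset:
    """Container of the six linked EMR tables over a study window.

    Invariants (checked by :meth:`validate`): unique patient and GP ids,
    resolvable foreign keys, event dates not after the window end, lab
    values positive and tagged with their analyte's canonical unit.
    """

    patients: pd.DataFrame
    gps: pd.DataFrame
    encounters: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    vitals: pd.DataFrame
    study_window: tuple[pd.Timestamp, pd.Timestamp] = (
        pd.Timestamp("2013-01-01"),
        pd.Timestamp("2019-12-31"),
    )

    def __post_init__(self) -> None:
        start, end = self.study_window
        self.study_window = (pd.Timestamp(start), pd.Timestamp(end))

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    def validate(self) -> "EmrDataset":
        for name, cols in TABLE_SCHEMAS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValidationError(f"table {name!r} lacks columns {missing}")
        if self.patients["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id")
        if self.gps["gp_id"].duplicated().any():
            raise ValidationError("duplicate gp_id")
        known_gps = set(self.gps["gp_id"])
        orphan = ~self.patients["gp_id"].isin(known_gps)
        if orphan.any():
            raise ValidationError(
                f"{int(orphan.sum())} patients reference unknown GPs"
            )
        known_patients = set(self.patients["patient_id"])
        _, end = self.study_window
        for name in EVENT_TABLES:
            df = getattr(self, name)
            if len(df) == 0:
                continue
            if not df["patient_id"].isin(known_patients).all():
                raise ValidationError(f"table {name!r} has unknown patient_id")
            dates = pd.to_datetime(df["date"])
            if (dates > end).any():
                raise ValidationError(f"table {name!r} has dates after window end")
        if len(self.labs):
            bad_unit = [
                (a, u)
                for a, u in self.labs[["analyte", "unit"]].drop_duplicates().itertuples(index=False)
                if CANONICAL_UNITS.get(a) != u
            ]
            if bad_unit:
                raise ValidationError(f"non-canonical lab units: {bad_unit}")
            if (self.labs["value"] <= 0).any():
                raise ValidationError("non-positive lab values")
        return self

    def patient_events(self, patient_id) -> dict[str, pd.DataFrame]:
        """All event rows for one patient, keyed by table name."""
        return {
            name: getattr(self, name).loc[
                getattr(self, name)["patient_id"] == patient_id
            ]
            for name in EVENT_TABLES
        }

    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables.items()}


def age_at(birth_year, when) -> float:
    """Year-resolution age: ``when.year - birth_year``.

    Accepts scalars or array-likes; missing birth years propagate as NaN.
    """
    if isinstance(when, (pd.Timestamp, _date)):
        year = when.year
    else:
        year = pd.to_datetime(when).year
    if np.ndim(birth_year) == 0:
        if birth_year is None or (isinstance(birth_year, float) and np.isnan(birth_year)):
            return np.nan
        return float(year) - float(birth_year)
    by = pd.to_numeric(pd.Series(birth_year), errors="coerce")
    return (float(year) - by).to_numpy()


def ages_at(birth_years: pd.Series, dates: pd.Series) -> pd.Series:
    """Vectorised per-row age: event year minus birth year (NaN propagates)."""
    years = pd.to_datetime(dates).dt.year
    by = pd.to_numeric(birth_years, errors="coerce")
    return years.to_numpy() - by.to_numpy()


def derive_bmi(vitals: pd.DataFrame) -> pd.Series:
    """BMI per row: recorded value, else weight / height_m^2 when derivable."""
    bmi = pd.to_numeric(vitals.get("bmi"), errors="coerce")
    weight = pd.to_numeric(vitals.get("weight"), errors="coerce")
    height = pd.to_numeric(vitals.get("height"), errors="coerce")
    derived = weight / (height / 100.0) ** 2
    return bmi.fillna(derived)


@dataclass
class IngestionReport:
    """Row bookkeeping of a :func:`ckdqi.io.read_emr_tables` run."""

    accepted: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)
    reject_reasons: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, table: str, n_accepted: int, reasons: dict[str, int]) -> None:
        self.accepted[table] = n_accepted
        self.rejected[table] = int(sum(reasons.values()))
        self.reject_reasons[table] = dict(reasons)

    def total_input(self, table: str) -> int:
        return self.accepted.get(table, 0) + self.rejected.get(table, 0)

    def to_dict(self) -> dict:
        return {
            "accepted": self.accepted,
            "rejected": self.rejected,
            "reject_reasons": self.reject_reasons,
        }
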