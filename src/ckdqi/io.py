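"""Reading and writing the delimited EMR tables.

``read_emr_tables`` ingests six CSV/TSV files into a validated
:class:`~ckdqi.datamodel.EmrDataset`: column names may be remapped via an
ingestion config, source units are converted to the canonical unit per
analyte, and rows violating the row-level contract (unparseable date,
non-positive value, malformed ATC code, unknown unit, dangling foreign key)
are dropped and counted in an :class:`~ckdqi.datamodel.IngestionReport`.
Missing required columns are a hard error; bad rows are not.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .datamodel import (
    ATC_PATTERN,
    CANONICAL_UNITS,
    GENDERS_GP,
    GENDERS_PATIENT,
    ICPC2_PATTERN,
    TABLE_SCHEMAS,
    EmrDataset,
    IngestionReport,
)


class TableConfig(BaseModel):
    """Per-table ingestion options: source->canonical column renames."""

    columns: dict[str, str] = Field(default_factory=dict)
    delimiter: str = ","


class IngestionConfig(BaseModel):
    """Ingestion options for a six-table EMR export.

    ``lab_units`` declares the source unit per analyte for files whose unit
    column is empty; units are otherwise taken from the rows themselves.
    """

    tables: dict[str, TableConfig] = Field(default_factory=dict)
    lab_units: dict[str, str] = Field(default_factory=dict)
    study_window: tuple[str, str] = ("2013-01-01", "2019-12-31")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IngestionConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _load_raw(path: str | Path, table: str, cfg: TableConfig) -> pd.DataFrame:
    df = pd.read_csv(path, sep=cfg.delimiter, dtype=str, keep_default_na=False)
    df = df.rename(columns=cfg.columns)
    missing = [c for c in TABLE_SCHEMAS[table] if c not in df.columns]
    if missing:
        raise ValueError(
            f"file {path!s} (table {table!r}) is missing required column(s) {missing}"
        )
    return df.replace({"": None})


def _parse_dates(raw: pd.Series, reasons: Counter, label: str = "unparseable_date"):
    parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        reasons[label] += int(bad.sum())
    return parsed, parsed.notna()


def _parse_number(raw: pd.Series) -> pd.Series:
    return pd.to_numeric(raw, errors="coerce")


def read_emr_tables(
    paths: Mapping[str, str | Path],
    config: IngestionConfig | Mapping | None = None,
) -> tuple[EmrDataset, IngestionReport]:
    """Read, clean, and link the six EMR tables.

    Parameters
    ----------
    paths
        Mapping with keys ``patients, gps, encounters, prescriptions, labs,
        vitals`` to delimited text files, each with a header row.
    config
        Optional :class:`IngestionConfig` (or plain mapping) with column
        renames and default source units.

    Returns
    -------
    (dataset, report)
        The validated dataset and the per-table accepted/rejected counts.
    """
    if config is None:
        config = IngestionConfig()
    elif not isinstance(config, IngestionConfig):
        config = IngestionConfig.model_validate(dict(config))

    missing_tables = [t for t in TABLE_SCHEMAS if t not in paths]
    if missing_tables:
        raise ValueError(f"paths missing table(s) {missing_tables}")
    for table, p in paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"table {table!r}: no such file {p!s}")

    report = IngestionReport()
    raw = {
        t: _load_raw(paths[t], t, config.tables.get(t, TableConfig()))
        for t in TABLE_SCHEMAS
    }
    window = (pd.Timestamp(config.study_window[0]), pd.Timestamp(config.study_window[1]))

    gps, n_in = _clean_gps(raw["gps"], report)
    known_gps = set(gps["gp_id"])
    patients = _clean_patients(raw["patients"], known_gps, report)
    known_patients = set(patients["patient_id"])

    encounters = _clean_encounters(raw["encounters"], known_patients, window, report)
    prescriptions = _clean_prescriptions(raw["prescriptions"], known_patients, window, report)
    labs = _clean_labs(raw["labs"], known_patients, window, config.lab_units, report)
    vitals = _clean_vitals(raw["vitals"], known_patients, window, report)

    dataset = EmrDataset(
        patients=patients,
        gps=gps,
        encounters=encounters,
        prescriptions=prescriptions,
        labs=labs,
        vitals=vitals,
        study_window=window,
    ).validate()
    return dataset, report


def _finish(df: pd.DataFrame, keep, reasons: Counter, report, table: str) -> pd.DataFrame:
    out = df.loc[keep].reset_index(drop=True)
    report.record(table, len(out), dict(reasons))
    return out


def _clean_gps(df: pd.DataFrame, report) -> tuple[pd.DataFrame, int]:
    reasons: Counter = Counter()
    keep = df["gp_id"].notna() & ~df["gp_id"].duplicated()
    reasons["missing_or_duplicate_id"] += int((~keep).sum())
    out = df.copy()
    out["gender"] = out["gender"].where(out["gender"].isin(GENDERS_GP), "unknown")
    out["birth_year"] = _parse_number(out["birth_year"])
    out["urban_location"] = out["urban_location"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    out = _finish(out[TABLE_SCHEMAS["gps"]], keep, reasons, report, "gps")
    return out, len(df)


def _clean_patients(df: pd.DataFrame, known_gps, report) -> pd.DataFrame:
    reasons: Counter = Counter()
    out = df.copy()
    keep = out["patient_id"].notna() & ~out["patient_id"].duplicated()
    reasons["missing_or_duplicate_id"] += int((~keep).sum())
    fk = out["gp_id"].isin(known_gps)
    reasons["unknown_gp"] += int((keep & ~fk).sum())
    keep &= fk
    ok_gender = out["gender"].isin(GENDERS_PATIENT)
    reasons["invalid_gender"] += int((keep & ~ok_gender).sum())
    keep &= ok_gender
    out["birth_year"] = _parse_number(out["birth_year"])
    return _finish(out[TABLE_SCHEMAS["patients"]], keep, reasons, report, "patients")


def _event_base(df, known_patients, window, reasons):
    keep = df["patient_id"].isin(known_patients)
    reasons["unknown_patient"] += int((~keep).sum())
    dates, ok = _parse_dates(df["date"], reasons)
    keep &= ok
    in_window = dates <= window[1]
    reasons["after_window_end"] += int((keep & ~in_window).sum())
    keep &= in_window
    return dates, keep


def _clean_encounters(df, known_patients, window, report) -> pd.DataFrame:
    reasons: Counter = Counter()
    out = df.copy()
    out["date"], keep = _event_base(out, known_patients, window, reasons)
    code = out["icpc2_code"]
    out["icpc2_code"] = code.where(code.isna() | code.str.match(ICPC2_PATTERN, na=False))
    return _finish(out[TABLE_SCHEMAS["encounters"]], keep, reasons, report, "encounters")


def _clean_prescriptions(df, known_patients, window, report) -> pd.DataFrame:
    reasons: Counter = Counter()
    out = df.copy()
    out["date"], keep = _event_base(out, known_patients, window, reasons)
    ok_atc = out["atc_code"].str.match(ATC_PATTERN, na=False)
    reasons["invalid_atc"] += int((keep & ~ok_atc).sum())
    keep &= ok_atc
    end, _ = _parse_dates(out["end_date"], Counter())  # bad end dates -> missing
    out["end_date"] = end
    return _finish(out[TABLE_SCHEMAS["prescriptions"]], keep, reasons, report, "prescriptions")


def _clean_labs(df, known_patients, window, lab_units, report) -> pd.DataFrame:
    reasons: Counter = Counter()
    out = df.copy()
    out["date"], keep = _event_base(out, known_patients, window, reasons)

    known = out["analyte"].isin(CANONICAL_UNITS)
    reasons["unknown_analyte"] += int((keep & ~known).sum())
    keep &= known

    out["value"] = _parse_number(out["value"])
    ok_val = out["value"] > 0
    reasons["non_positive_value"] += int((keep & ~ok_val).sum())
    keep &= ok_val

    unit = out["unit"]
    unit = unit.fillna(out["analyte"].map(lab_units))
    unit = unit.fillna(out["analyte"].map(CANONICAL_UNITS))
    canonical = out["analyte"].map(CANONICAL_UNITS)
    is_canonical = unit == canonical
    factor = pd.Series(
        [
            _conversion_factor(a, u) if not c else 1.0
            for a, u, c in zip(out["analyte"], unit, is_canonical)
        ],
        index=out.index,
    )
    convertible = factor.notna()
    reasons["unknown_unit"] += int((keep & ~convertible).sum())
    keep &= convertible
    out["value"] = out["value"] * factor
    out["unit"] = canonical
    return _finish(out[TABLE_SCHEMAS["labs"]], keep, reasons, report, "labs")


def _conversion_factor(analyte: str, unit) -> float | None:
    from .datamodel import UNIT_CONVERSIONS

    if unit is None:
        return None
    return UNIT_CONVERSIONS.get((analyte, unit))


def _clean_vitals(df, known_patients, window, report) -> pd.DataFrame:
    reasons: Counter = Counter()
    out = df.copy()
    out["date"], keep = _event_base(out, known_patients, window, reasons)
    measure_cols = ["systolic_bp", "diastolic_bp", "weight", "height", "bmi"]
    for c in measure_cols:
        out[c] = _parse_number(out[c])
    any_measure = out[measure_cols].notna().any(axis=1)
    reasons["no_measurement"] += int((keep & ~any_measure).sum())
    keep &= any_measure
    return _finish(out[TABLE_SCHEMAS["vitals"]], keep, reasons, report, "vitals")


# ---------------------------------------------------------------------------
# writing

_DATE_COLS = ("date", "end_date", "index_date", "evidence_date")


def write_table(rows, path: str | Path, format: str = "csv") -> Path:
    """Write a result table as UTF-8 delimited text with a header row.

    Accepts a DataFrame or an iterable of dicts. Column order is the
    DataFrame's order (or first-dict key order) — deterministic either way.
    Dates are serialised as ISO ``YYYY-MM-DD``.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"unsupported format {format!r}")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df = df.copy()
    for col in df.columns:
        if col in _DATE_COLS or pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = pd.to_datetime(df[col], errors="coerce").dt.strftime("%Y-%m-%d")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="," if format == "csv" else "\t", index=False, encoding="utf-8")
    return path


def write_emr_tables(dataset: EmrDataset, out_dir: str | Path, format: str = "csv") -> dict[str, Path]:
    """Write all six tables of a dataset; returns the table->path map."""
    out_dir = Path(out_dir)
    ext = "csv" if format == "csv" else "tsv"
    paths = {}
    for name, df in dataset.tables.items():
        paths[name] = write_table(df, out_dir / f"{name}.{ext}", format=format)
    return paths


def write_ingestion_report(report: IngestionReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return path
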