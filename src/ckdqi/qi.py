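"""The fourteen quality indicators (QIs) for CKD care.

Four categories share one evaluation pattern — a denominator population
defined on a cohort, and a numerator predicate over the patient's events:

* *Assessment* (QIs 1-3, 18-month window): renal-function (RF) testing
  after first identification of diabetes / hypertension / eCVD.
* *Monitoring* (QIs 4-8, 18-month window): stage-appropriate follow-up
  testing after CKD confirmation.
* *Medication* (QIs 9-11, 12-month window): RAAS-inhibitor and statin
  prescribing; withholding NSAIDs.
* *Treatment target* (QIs 12-14, no window): the latest blood-pressure or
  BMI measurement after CKD confirmation lies in the target range.

Event semantics: an RF assessment is any serum-creatinine/eGFR or
albuminuria (ACR/UAC) measurement; an albuminuria assessment is ACR or
UAC; CBC is a haemoglobin measurement; blood chemistry is urea, sodium or
potassium; the mineral-and-bone screen is alkaline phosphatase, calcium,
phosphate or parathyroid hormone. Medication classes are ATC prefixes.

For monitoring QIs only events strictly after the index date count (the
CKD-confirming measurement does not double as its own follow-up); for
assessment and medication QIs the window is closed at the index date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import DAYS_12_MONTHS, DAYS_18_MONTHS
from .datamodel import EmrDataset, ages_at, derive_bmi

G1_4 = ("G1", "G2", "G3a", "G3b", "G4")
G2_4 = ("G2", "G3a", "G3b", "G4")
G3A_4 = ("G3a", "G3b", "G4")
G3B_4 = ("G3b", "G4")
G2_3B = ("G2", "G3a", "G3b")

RF_ANALYTES = ("serum_creatinine", "egfr", "acr", "uac")
SCR_EGFR = ("serum_creatinine", "egfr")
ALBUMINURIA = ("acr", "uac")
CBC = ("hemoglobin",)
CHEMISTRY = ("urea", "sodium", "potassium")
MBD = ("alkaline_phosphatase", "calcium", "phosphate", "parathyroid_hormone")


@dataclass(frozen=True)
class QiConfig:
    """Externalised QI parameters (ATC sets, thresholds, windows)."""

    window_18m_days: int = DAYS_18_MONTHS
    window_12m_days: int = DAYS_12_MONTHS
    raas_prefixes: tuple[str, ...] = ("C09",)
    statin_prefixes: tuple[str, ...] = ("C10AA", "C10B")
    nsaid_prefixes: tuple[str, ...] = ("M01A",)
    #: aspirin-containing / combination codes never counted as NSAIDs
    nsaid_exclude_prefixes: tuple[str, ...] = ("M01BA", "B01AC06", "N02BA01")
    bp_target: tuple[float, float] = (140.0, 90.0)
    bp_target_diabetes: tuple[float, float] = (130.0, 80.0)
    bmi_range: tuple[float, float] = (20.0, 25.0)
    statin_age_range: tuple[float, float] = (50.0, 80.0)
    #: monitoring QIs count only events strictly after the index date
    monitoring_excludes_index_date: bool = True


@dataclass(frozen=True)
class QiDefinition:
    qi_id: int
    category: str
    description: str
    window_months: int | None


QI_DEFINITIONS: dict[int, QiDefinition] = {
    1: QiDefinition(1, "assessment", "RF; diabetes (18)", 18),
    2: QiDefinition(2, "assessment", "RF; hypertension (18)", 18),
    3: QiDefinition(3, "assessment", "RF; eCVD (18)", 18),
    4: QiDefinition(4, "monitoring", "eGFR/SCr; G1-4 (18)", 18),
    5: QiDefinition(5, "monitoring", "ACR/UAC; G1-4 (18)", 18),
    6: QiDefinition(6, "monitoring", "RF+BP; G2-4 (18)", 18),
    7: QiDefinition(7, "monitoring", "RF+BP+CBC+chem; G3a-4 (18)", 18),
    8: QiDefinition(8, "monitoring", "RF+BP+CBC+chem+MBD; G3b-4 (18)", 18),
    9: QiDefinition(9, "medication", "RAAS inhibitor; G1-4 (12)", 12),
    10: QiDefinition(10, "medication", "Statin; G1-4, 50-80 years (12)", 12),
    11: QiDefinition(11, "medication", "Withheld NSAID; G2-3b (12)", 12),
    12: QiDefinition(12, "treatment_target", "Latest BP < 140/90 mmHg; G1-4", None),
    13: QiDefinition(13, "treatment_target", "Latest BP < 130/80 mmHg; G1-4, diabetes", None),
    14: QiDefinition(14, "treatment_target", "Latest BMI 20-25 kg/m2; G1-4", None),
}


@dataclass
class QiResult:
    """Per-patient flags and the aggregate achievement rate for one QI."""

    qi_id: int
    category: str
    description: str
    per_patient: pd.DataFrame  # columns: patient_id, gp_id, achieved, index_date
    achievement_rate: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.per_patient)
        self.achievement_rate = (
            100.0 * float(self.per_patient["achieved"].sum()) / n if n else float("nan")
        )


# ---------------------------------------------------------------------------
# event-window helpers


def _flag_in_window(
    events: pd.DataFrame,
    members: pd.DataFrame,
    window_days: int | None,
    include_index: bool,
) -> pd.Series:
    """Boolean per member row: any event in the member's window.

    Window is [index, index + window_days) — or (index, index + window_days)
    when ``include_index`` is False; an open-ended window when
    ``window_days`` is None.
    """
    if len(events) == 0 or len(members) == 0:
        return pd.Series(False, index=members.index)
    m = members.reset_index()[["index", "patient_id", "index_date"]]
    merged = m.merge(events[["patient_id", "date"]], on="patient_id", how="inner")
    lower_ok = (
        merged["date"] >= merged["index_date"]
        if include_index
        else merged["date"] > merged["index_date"]
    )
    if window_days is None:
        in_win = lower_ok
    else:
        in_win = lower_ok & (
            merged["date"] < merged["index_date"] + pd.Timedelta(days=window_days)
        )
    hit = merged.loc[in_win, "index"].unique()
    out = pd.Series(False, index=members.index)
    out.loc[hit] = True
    return out


def _lab_events(dataset: EmrDataset, analytes) -> pd.DataFrame:
    labs = dataset.labs
    return labs.loc[labs["analyte"].isin(analytes), ["patient_id", "date"]]


def _bp_events(dataset: EmrDataset, complete: bool = False) -> pd.DataFrame:
    vit = dataset.vitals
    has = (
        vit["systolic_bp"].notna() & vit["diastolic_bp"].notna()
        if complete
        else vit["systolic_bp"].notna() | vit["diastolic_bp"].notna()
    )
    cols = ["patient_id", "date", "systolic_bp", "diastolic_bp"]
    return vit.loc[has, cols]


def _active_prescriptions_in_window(
    rx: pd.DataFrame, members: pd.DataFrame, window_days: int
) -> pd.Series:
    """Any prescription active within [index, index + window): start date in
    the window, or a [start, end] interval overlapping it."""
    if len(rx) == 0 or len(members) == 0:
        return pd.Series(False, index=members.index)
    m = members.reset_index()[["index", "patient_id", "index_date"]]
    merged = m.merge(
        rx[["patient_id", "date", "end_date"]], on="patient_id", how="inner"
    )
    win_end = merged["index_date"] + pd.Timedelta(days=window_days)
    starts_in = (merged["date"] >= merged["index_date"]) & (merged["date"] < win_end)
    overlaps = (
        merged["end_date"].notna()
        & (merged["date"] < win_end)
        & (merged["end_date"] >= merged["index_date"])
    )
    hit = merged.loc[starts_in | overlaps, "index"].unique()
    out = pd.Series(False, index=members.index)
    out.loc[hit] = True
    return out


def _rx_by_prefix(dataset: EmrDataset, prefixes, exclude=()) -> pd.DataFrame:
    rx = dataset.prescriptions
    sel = rx["atc_code"].str.startswith(tuple(prefixes), na=False)
    if exclude:
        sel &= ~rx["atc_code"].str.startswith(tuple(exclude), na=False)
    return rx.loc[sel]


def _latest_value_after_index(
    rows: pd.DataFrame, members: pd.DataFrame, value_cols: list[str]
) -> pd.DataFrame:
    """Latest measurement per member at/after the index date.

    Returns one row per member (aligned to ``members.index``) with the
    requested value columns; members without any qualifying measurement
    are absent.
    """
    if len(rows) == 0 or len(members) == 0:
        return pd.DataFrame(columns=value_cols)
    m = members.reset_index()[["index", "patient_id", "index_date"]]
    merged = m.merge(rows, on="patient_id", how="inner")
    merged = merged.loc[merged["date"] >= merged["index_date"]]
    if len(merged) == 0:
        return pd.DataFrame(columns=value_cols)
    merged = merged.sort_values(["index", "date"], kind="stable")
    latest = merged.groupby("index").tail(1).set_index("index")
    return latest[value_cols]


# ---------------------------------------------------------------------------
# denominators


def _stage_denominator(ckd: pd.DataFrame, stages, min_followup_days: int | None):
    sel = ckd["g_stage_at_inclusion"].isin(stages)
    if min_followup_days is not None:
        followup_days = ckd["followup_months"] * 30.4375
        sel &= followup_days.round(6) >= min_followup_days
    return ckd.loc[sel].copy()


def evaluate_qi(
    qi_id: int,
    cohorts: dict[str, pd.DataFrame],
    dataset: EmrDataset,
    config: QiConfig = QiConfig(),
) -> QiResult:
    """Evaluate one QI; ``cohorts`` holds the ``rf`` and ``ckd`` tables."""
    if qi_id not in QI_DEFINITIONS:
        raise ValueError(f"unknown QI id {qi_id!r}")
    qdef = QI_DEFINITIONS[qi_id]
    rf_cohort = cohorts["rf"]
    ckd_cohort = cohorts["ckd"]
    w18, w12 = config.window_18m_days, config.window_12m_days
    after_index = not config.monitoring_excludes_index_date  # include index?

    if qi_id in (1, 2, 3):
        cond = {1: "diabetes", 2: "hypertension", 3: "ecvd"}[qi_id]
        denom = rf_cohort.loc[rf_cohort[f"eligible_{cond}"]].copy()
        denom["index_date"] = denom[f"index_{cond}"]
        achieved = _flag_in_window(
            _lab_events(dataset, RF_ANALYTES), denom, w18, include_index=True
        )
    elif qi_id in (4, 5, 6, 7, 8):
        stages = {4: G1_4, 5: G1_4, 6: G2_4, 7: G3A_4, 8: G3B_4}[qi_id]
        denom = _stage_denominator(ckd_cohort, stages, w18)
        parts = {
            4: [SCR_EGFR],
            5: [ALBUMINURIA],
            6: [RF_ANALYTES, "bp"],
            7: [RF_ANALYTES, "bp", CBC, CHEMISTRY],
            8: [RF_ANALYTES, "bp", CBC, CHEMISTRY, MBD],
        }[qi_id]
        achieved = pd.Series(True, index=denom.index)
        for part in parts:
            events = (
                _bp_events(dataset) if part == "bp" else _lab_events(dataset, part)
            )
            achieved &= _flag_in_window(events, denom, w18, include_index=after_index)
    elif qi_id == 9:
        denom = _stage_denominator(ckd_cohort, G1_4, w12)
        rx = _rx_by_prefix(dataset, config.raas_prefixes)
        achieved = _active_prescriptions_in_window(rx, denom, w12)
    elif qi_id == 10:
        denom = _stage_denominator(ckd_cohort, G1_4, w12)
        age = ages_at(denom["birth_year"], denom["index_date"])
        lo, hi = config.statin_age_range
        denom = denom.loc[(age >= lo) & (age <= hi)].copy()
        rx = _rx_by_prefix(dataset, config.statin_prefixes)
        achieved = _active_prescriptions_in_window(rx, denom, w12)
    elif qi_id == 11:
        denom = _stage_denominator(ckd_cohort, G2_3B, w12)
        rx = _rx_by_prefix(
            dataset, config.nsaid_prefixes, exclude=config.nsaid_exclude_prefixes
        )
        achieved = ~_active_prescriptions_in_window(rx, denom, w12)
    elif qi_id in (12, 13):
        base = _stage_denominator(ckd_cohort, G1_4, None)
        if qi_id == 13:
            base = base.loc[base["has_diabetes"]].copy()
        bp = _bp_events(dataset, complete=True)
        latest = _latest_value_after_index(bp, base, ["systolic_bp", "diastolic_bp"])
        denom = base.loc[base.index.isin(latest.index)].copy()
        sys_t, dia_t = (
            config.bp_target if qi_id == 12 else config.bp_target_diabetes
        )
        vals = latest.loc[denom.index]
        achieved = (vals["systolic_bp"] < sys_t) & (vals["diastolic_bp"] < dia_t)
    elif qi_id == 14:
        base = _stage_denominator(ckd_cohort, G1_4, None)
        vit = dataset.vitals.copy()
        vit["bmi_value"] = derive_bmi(vit)
        rows = vit.loc[vit["bmi_value"].notna(), ["patient_id", "date", "bmi_value"]]
        latest = _latest_value_after_index(rows, base, ["bmi_value"])
        denom = base.loc[base.index.isin(latest.index)].copy()
        lo, hi = config.bmi_range
        vals = latest.loc[denom.index, "bmi_value"]
        achieved = (vals >= lo) & (vals <= hi)

    per_patient = denom[["patient_id", "gp_id", "index_date"]].copy()
    per_patient["achieved"] = achieved.reindex(denom.index).fillna(False).astype(bool).to_numpy()
    return QiResult(
        qi_id=qi_id,
        category=qdef.category,
        description=qdef.description,
        per_patient=per_patient.reset_index(drop=True),
    )


def evaluate_all(
    cohorts: dict[str, pd.DataFrame],
    dataset: EmrDataset,
    config: QiConfig = QiConfig(),
) -> tuple[list[QiResult], pd.DataFrame]:
    """All 14 QIs plus a summary table (category, qi_id, description, rate)."""
    results = [evaluate_qi(i, cohorts, dataset, config) for i in QI_DEFINITIONS]
    summary = pd.DataFrame(
        {
            "category": [r.category for r in results],
            "qi_id": [r.qi_id for r in results],
            "description": [r.description for r in results],
            "n_denominator": [len(r.per_patient) for r in results],
            "achievement_rate": [r.achievement_rate for r in results],
        }
    )
    return results, summary
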