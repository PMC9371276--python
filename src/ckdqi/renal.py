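"""Renal function: CKD-EPI eGFR, KDIGO staging, and laboratory CKD detection.

The estimated glomerular filtration rate (eGFR) is computed with the 2009
CKD-EPI creatinine equation. No ethnicity coefficient is applied — the data
model carries no ethnicity field, so the equation reduces to its
sex/age/creatinine terms:

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age * s

with serum creatinine Scr in mg/dL, k = 0.7 (female) / 0.9 (male),
a = -0.329 (female) / -0.411 (male), and s = 1.018 for female patients.

A patient is labelled as having laboratory-confirmed chronic kidney disease
upon two eGFR values < 60 mL/min/1.73m2, and/or two urinary albumin
concentrations (UAC) >= 20 mg/L, and/or two albumin-to-creatinine ratios
(ACR) >= 3 mg/mmol, at least three months (90 days) apart — each criterion
evaluated on its own analyte series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import EmrDataset, ages_at

UMOL_PER_MGDL = 88.42

G_STAGE_EDGES = (15.0, 30.0, 45.0, 60.0, 90.0)  # lower edges of G4..G1
G_STAGE_LABELS = ("G5", "G4", "G3b", "G3a", "G2", "G1")
A_STAGE_LABELS = ("A1", "A2", "A3")


@dataclass(frozen=True)
class DetectionThresholds:
    """CKD case-detection rule parameters (defaults per KDIGO practice)."""

    egfr_below: float = 60.0       # mL/min/1.73m2
    uac_at_least: float = 20.0     # mg/L
    acr_at_least: float = 3.0      # mg/mmol
    min_gap_days: int = 90         # "at least 3 months apart"
    g5_below: float = 15.0


@dataclass
class CkdEvidence:
    """Outcome of the case-detection rule for one patient."""

    patient_id: object
    ckd_confirmed: bool
    evidence_date: pd.Timestamp | None = None
    criterion: str | None = None            # 'egfr' | 'uac' | 'acr'
    g_stage_at_inclusion: str | None = None
    a_stage_at_inclusion: str | None = None
    ever_g5: bool = False


def ckd_epi_egfr(scr_umol, age, sex):
    """2009 CKD-EPI creatinine eGFR, in mL/min/1.73 m2.

    Parameters
    ----------
    scr_umol
        Serum creatinine in umol/L (scalar or array).
    age
        Age in years (>= 18 for validity of the adult equation).
    sex
        ``'female'`` or ``'male'`` (scalar or array). Any other value
        yields NaN: the creatinine equation is sex-specific, so no
        derived eGFR exists for patients of other gender.
    """
    scr = np.asarray(scr_umol, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")

    female = sex == "female"
    male = sex == "male"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = (scr / UMOL_PER_MGDL) / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
    )
    egfr = np.where(female | male, egfr, np.nan)
    return float(egfr) if egfr.ndim == 0 else egfr


def stage_g(egfr):
    """KDIGO G stage from eGFR: G1 >=90, G2 60-89, G3a 45-59, G3b 30-44,
    G4 15-29, G5 <15 (lower edges inclusive)."""
    arr = np.asarray(egfr, dtype=float)
    if np.any(arr < 0):
        raise ValueError("eGFR must be non-negative")
    idx = np.searchsorted(G_STAGE_EDGES, arr, side="right")
    out = np.asarray(G_STAGE_LABELS)[idx]
    return str(out) if arr.ndim == 0 else out


def stage_a(acr):
    """KDIGO A stage from ACR (mg/mmol): A1 <3, A2 3-30, A3 >30."""
    arr = np.asarray(acr, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ACR must be non-negative")
    idx = np.searchsorted([3.0, 30.0], arr, side="right")
    # exactly 30 belongs to A2
    idx = np.where(arr == 30.0, 1, idx)
    out = np.asarray(A_STAGE_LABELS)[idx]
    return str(out) if arr.ndim == 0 else out


def _confirming_date(dates: np.ndarray, gap_days: int):
    """Earliest second-of-pair date among qualifying dates >= gap apart."""
    if len(dates) < 2:
        return None
    first = dates.min()
    later = dates[dates >= first + np.timedelta64(gap_days, "D")]
    if len(later) == 0:
        return None
    return pd.Timestamp(later.min())


def detect_ckd(
    series: pd.DataFrame,
    patient_id=None,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> CkdEvidence:
    """Apply the two-abnormal-values rule to one patient's measurements.

    ``series`` needs columns ``date`` and any of ``egfr``, ``acr``, ``uac``
    (NaN where a measurement is absent). Each criterion is evaluated on its
    own series; the evidence date is the earliest confirming
    (second-of-pair) date across criteria. Ties between criteria on the
    same date resolve in the order eGFR, UAC, ACR.
    """
    if len(series) == 0:
        return CkdEvidence(patient_id=patient_id, ckd_confirmed=False)
    dates = pd.to_datetime(series["date"]).to_numpy()

    def qualifying(col, pred):
        if col not in series:
            return np.array([], dtype="datetime64[ns]")
        vals = pd.to_numeric(series[col], errors="coerce").to_numpy(dtype=float)
        mask = pred(vals) & ~np.isnan(vals)
        return dates[mask]

    candidates = {
        "egfr": _confirming_date(
            qualifying("egfr", lambda v: v < thresholds.egfr_below), thresholds.min_gap_days
        ),
        "uac": _confirming_date(
            qualifying("uac", lambda v: v >= thresholds.uac_at_least), thresholds.min_gap_days
        ),
        "acr": _confirming_date(
            qualifying("acr", lambda v: v >= thresholds.acr_at_least), thresholds.min_gap_days
        ),
    }
    ever_g5 = False
    if "egfr" in series:
        egfr_vals = pd.to_numeric(series["egfr"], errors="coerce")
        ever_g5 = bool((egfr_vals < thresholds.g5_below).any())

    firing = {c: d for c, d in candidates.items() if d is not None}
    if not firing:
        return CkdEvidence(patient_id=patient_id, ckd_confirmed=False, ever_g5=ever_g5)
    criterion = min(firing, key=lambda c: (firing[c], ("egfr", "uac", "acr").index(c)))
    evidence_date = firing[criterion]

    g_stage = _stage_at(series, dates, evidence_date, "egfr", stage_g)
    a_stage = _stage_at(series, dates, evidence_date, "acr", stage_a)
    return CkdEvidence(
        patient_id=patient_id,
        ckd_confirmed=True,
        evidence_date=evidence_date,
        criterion=criterion,
        g_stage_at_inclusion=g_stage,
        a_stage_at_inclusion=a_stage,
        ever_g5=ever_g5,
    )


def _stage_at(series, dates, when, col, stager):
    """Stage of the most recent ``col`` measurement at or before ``when``."""
    if col not in series:
        return None
    vals = pd.to_numeric(series[col], errors="coerce").to_numpy(dtype=float)
    mask = ~np.isnan(vals) & (dates <= np.datetime64(when))
    if not mask.any():
        return None
    latest = dates[mask].max()
    at_latest = vals[mask & (dates == latest)]
    return stager(float(at_latest[-1]))


def rf_measurements(dataset: EmrDataset) -> pd.DataFrame:
    """Per-patient renal-function series from the lab table.

    Returns one row per (patient, date) with columns ``egfr``, ``acr``,
    ``uac``. Reported eGFR takes precedence; where a creatinine value
    exists without a same-day reported eGFR, eGFR is derived via CKD-EPI
    (female/male patients only).
    """
    labs = dataset.labs
    rf = labs[labs["analyte"].isin(["serum_creatinine", "egfr", "acr", "uac"])]
    if len(rf) == 0:
        return pd.DataFrame(columns=["patient_id", "date", "egfr", "acr", "uac"])
    wide = (
        rf.pivot_table(
            index=["patient_id", "date"],
            columns="analyte",
            values="value",
            aggfunc="last",
        )
        .reindex(columns=["egfr", "serum_creatinine", "acr", "uac"])
        .reset_index()
    )
    wide.columns.name = None

    demo = dataset.patients.set_index("patient_id")[["gender", "birth_year"]]
    gender = wide["patient_id"].map(demo["gender"])
    birth_year = wide["patient_id"].map(demo["birth_year"])
    need = wide["egfr"].isna() & wide["serum_creatinine"].notna()
    if need.any():
        ages = ages_at(birth_year[need], wide.loc[need, "date"])
        derivable = gender[need].isin(["female", "male"]).to_numpy() & (ages >= 18)
        derived = np.full(int(need.sum()), np.nan)
        if derivable.any():
            derived[derivable] = ckd_epi_egfr(
                wide.loc[need, "serum_creatinine"].to_numpy()[derivable],
                ages[derivable],
                gender[need].to_numpy()[derivable],
            )
        wide.loc[need, "egfr"] = derived
    return wide[["patient_id", "date", "egfr", "acr", "uac"]].sort_values(
        ["patient_id", "date"], kind="stable"
    )


def detect_ckd_all(
    dataset: EmrDataset, thresholds: DetectionThresholds = DetectionThresholds()
) -> pd.DataFrame:
    """Run case detection for every patient; one row per patient.

    Columns: patient_id, ckd_confirmed, evidence_date, criterion,
    g_stage_at_inclusion, a_stage_at_inclusion, ever_g5.
    """
    series = rf_measurements(dataset)
    records = []
    for pid, grp in series.groupby("patient_id", sort=False):
        records.append(detect_ckd(grp, patient_id=pid, thresholds=thresholds).__dict__)
    confirmed = pd.DataFrame(
        records,
        columns=[
            "patient_id",
            "ckd_confirmed",
            "evidence_date",
            "criterion",
            "g_stage_at_inclusion",
            "a_stage_at_inclusion",
            "ever_g5",
        ],
    )
    # patients with no RF measurements at all
    missing = dataset.patients.loc[
        ~dataset.patients["patient_id"].isin(confirmed["patient_id"]), ["patient_id"]
    ].copy()
    missing["ckd_confirmed"] = False
    missing["ever_g5"] = False
    out = pd.concat([confirmed, missing], ignore_index=True)
    out["ckd_confirmed"] = out["ckd_confirmed"].astype(bool)
    out["ever_g5"] = out["ever_g5"].astype(bool)
    return out.reset_index(drop=True)
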