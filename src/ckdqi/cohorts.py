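"""Cohort construction.

Three nested populations are built from a validated EMR dataset:

* **baseline** — every patient with at least one consultation in the study
  window and aged >= 18 at first observation;
* **renal-function (RF) assessment cohort** — baseline patients with at
  least 18 months between first evidence of a predisposing condition
  (diabetes, hypertension, eCVD) and their last recorded contact, kept
  per-condition so each assessment indicator uses its own index date;
* **CKD care cohort** — baseline patients with laboratory-confirmed CKD,
  excluding anyone ever staged G5 (eGFR < 15), indexed at the confirming
  measurement's date.

Follow-up runs from the index date to the last recorded contact of any
event type. Month windows use fixed day counts (18 months = 548 days,
12 months = 365 days; a month is 30.4375 days when expressing follow-up
in months), keeping all window arithmetic at day resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import CONDITIONS
from .datamodel import EVENT_TABLES, EmrDataset, ages_at

DAYS_PER_MONTH = 30.4375
DAYS_18_MONTHS = 548
DAYS_12_MONTHS = 365


@dataclass(frozen=True)
class FollowupWindows:
    """Window constants in days; configurable in one place."""

    months_18: int = DAYS_18_MONTHS
    months_12: int = DAYS_12_MONTHS


def last_contact(dataset: EmrDataset) -> pd.Series:
    """Latest event date of any type per patient (index: patient_id)."""
    pieces = []
    for name in EVENT_TABLES:
        df = getattr(dataset, name)
        if len(df):
            pieces.append(df[["patient_id", "date"]])
    if not pieces:
        return pd.Series(dtype="datetime64[ns]", name="last_contact")
    allev = pd.concat(pieces, ignore_index=True)
    out = allev.groupby("patient_id")["date"].max()
    out.name = "last_contact"
    return out


def first_observation(dataset: EmrDataset) -> pd.Series:
    """Earliest event date of any type per patient."""
    pieces = [
        getattr(dataset, name)[["patient_id", "date"]]
        for name in EVENT_TABLES
        if len(getattr(dataset, name))
    ]
    if not pieces:
        return pd.Series(dtype="datetime64[ns]")
    return pd.concat(pieces, ignore_index=True).groupby("patient_id")["date"].min()


def build_baseline(dataset: EmrDataset) -> pd.DataFrame:
    """Baseline population: >= 1 encounter in window, adult at first observation.

    Returns the patients table restricted to qualifying patients, with
    ``first_observation`` and ``last_contact`` columns attached.
    """
    start, end = dataset.study_window
    enc = dataset.encounters
    in_window = enc.loc[(enc["date"] >= start) & (enc["date"] <= end), "patient_id"]
    has_consultation = dataset.patients["patient_id"].isin(set(in_window))

    first_obs = first_observation(dataset)
    pts = dataset.patients.copy()
    pts["first_observation"] = pts["patient_id"].map(first_obs)
    pts["last_contact"] = pts["patient_id"].map(last_contact(dataset))
    age_first = ages_at(pts["birth_year"], pts["first_observation"])
    adult = age_first >= 18
    return pts.loc[has_consultation.to_numpy() & adult].reset_index(drop=True)


def build_rf_cohort(
    baseline: pd.DataFrame,
    timelines: pd.DataFrame,
    windows: FollowupWindows = FollowupWindows(),
) -> pd.DataFrame:
    """RF assessment cohort with per-condition eligibility flags.

    One row per cohort member. ``eligible_<cond>`` marks >= 18 months of
    follow-up after that condition's first evidence; ``index_<cond>``
    carries the condition-specific index date. Membership requires
    eligibility for at least one condition. ``index_date`` is the earliest
    eligible condition's evidence date.
    """
    df = baseline.merge(timelines, on="patient_id", how="left")
    horizon = pd.Timedelta(days=windows.months_18)
    index_cols = []
    for cond in CONDITIONS:
        first = df[f"first_{cond}"]
        df[f"eligible_{cond}"] = first.notna() & (df["last_contact"] - first >= horizon)
        df[f"index_{cond}"] = first.where(df[f"eligible_{cond}"])
        index_cols.append(f"index_{cond}")
    member = df[[f"eligible_{c}" for c in CONDITIONS]].any(axis=1)
    out = df.loc[member].copy()
    out["cohort"] = "rf_assessment"
    out["index_date"] = out[index_cols].min(axis=1)
    out["followup_months"] = (
        (out["last_contact"] - out["index_date"]).dt.days / DAYS_PER_MONTH
    )
    for cond in CONDITIONS:
        out[f"has_{cond}"] = out[f"first_{cond}"].notna()
    return out.reset_index(drop=True)


def build_ckd_cohort(
    baseline: pd.DataFrame,
    evidence: pd.DataFrame,
    timelines: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """CKD care cohort: confirmed patients, never staged G5.

    Index date is the confirmation (second abnormal measurement) date;
    G/A stages at inclusion and condition flags (first evidence at or
    before the index date, plus ``has_<cond>`` for evidence anywhere in
    the window) are attached.
    """
    ev = evidence.loc[evidence["ckd_confirmed"] & ~evidence["ever_g5"]]
    out = baseline.merge(
        ev[
            [
                "patient_id",
                "evidence_date",
                "criterion",
                "g_stage_at_inclusion",
                "a_stage_at_inclusion",
            ]
        ],
        on="patient_id",
        how="inner",
    )
    out["cohort"] = "ckd_care"
    out["index_date"] = out["evidence_date"]
    out["followup_months"] = (
        (out["last_contact"] - out["index_date"]).dt.days / DAYS_PER_MONTH
    )
    if timelines is not None:
        out = out.merge(timelines, on="patient_id", how="left")
        for cond in CONDITIONS:
            first = out[f"first_{cond}"]
            out[f"has_{cond}"] = first.notna()
            out[f"{cond}_at_index"] = first.notna() & (first <= out["index_date"])
    return out.reset_index(drop=True)
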