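"""Quality-indicator engine: windows, event semantics, and an independent
per-patient recount oracle."""

import numpy as np
import pandas as pd
import pytest

from ckdqi.cohorts import build_baseline, build_ckd_cohort, build_rf_cohort
from ckdqi.conditions import label_conditions
from ckdqi.datamodel import derive_bmi
from ckdqi.qi import QI_DEFINITIONS, QiConfig, evaluate_all, evaluate_qi
from ckdqi.renal import detect_ckd_all

from conftest import make_dataset


def _single_ckd_member(g_stage="G3a", followup_months=24.0, has_diabetes=False):
    return pd.DataFrame(
        [
            {
                "patient_id": "P1",
                "gp_id": "G1",
                "gender": "female",
                "birth_year": 1950.0,
                "cohort": "ckd_care",
                "index_date": pd.Timestamp("2015-01-01"),
                "followup_months": followup_months,
                "g_stage_at_inclusion": g_stage,
                "a_stage_at_inclusion": None,
                "has_diabetes": has_diabetes,
                "has_hypertension": False,
                "has_ecvd": False,
            }
        ]
    )


def _cohorts(ckd=None, rf=None):
    empty_rf = pd.DataFrame(
        columns=[
            "patient_id", "gp_id", "gender", "birth_year", "index_date",
            "eligible_diabetes", "eligible_hypertension", "eligible_ecvd",
            "index_diabetes", "index_hypertension", "index_ecvd",
        ]
    )
    empty_ckd = _single_ckd_member().iloc[:0]
    return {"rf": rf if rf is not None else empty_rf,
            "ckd": ckd if ckd is not None else empty_ckd}


class TestMedication:
    def test_nsaid_withheld_when_no_prescription(self):
        ds = make_dataset()
        res = evaluate_qi(11, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0

    def test_nsaid_in_window_fails_qi11(self):
        ds = make_dataset(
            prescriptions=[{"patient_id": "P1", "date": "2015-06-01", "atc_code": "M01AB05"}]
        )
        res = evaluate_qi(11, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 0.0

    def test_aspirin_does_not_count_as_nsaid(self):
        ds = make_dataset(
            prescriptions=[{"patient_id": "P1", "date": "2015-06-01", "atc_code": "B01AC06"}]
        )
        res = evaluate_qi(11, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0

    def test_nsaid_outside_window_ignored(self):
        ds = make_dataset(
            prescriptions=[{"patient_id": "P1", "date": "2016-02-01", "atc_code": "M01AE01"}]
        )
        res = evaluate_qi(11, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0

    def test_overlapping_interval_counts_as_active(self):
        ds = make_dataset(
            prescriptions=[
                {"patient_id": "P1", "date": "2014-06-01", "atc_code": "C09AA02",
                 "end_date": "2015-03-01"}
            ]
        )
        res = evaluate_qi(9, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0

    def test_g1_not_in_qi11_denominator(self):
        ds = make_dataset()
        res = evaluate_qi(11, _cohorts(ckd=_single_ckd_member(g_stage="G1")), ds)
        assert len(res.per_patient) == 0

    def test_statin_age_restriction(self):
        member = _single_ckd_member()
        member["birth_year"] = 1990.0  # age 25 at index
        res = evaluate_qi(10, _cohorts(ckd=member), make_dataset())
        assert len(res.per_patient) == 0


class TestMonitoring:
    def test_albuminuria_within_window_achieves_qi5(self):
        ds = make_dataset(
            labs=[{"patient_id": "P1", "date": "2015-07-01", "analyte": "uac", "value": 15.0}]
        )
        res = evaluate_qi(5, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0

    def test_albuminuria_after_window_fails_qi5(self):
        # index + 19 months is beyond the 548-day window
        ds = make_dataset(
            labs=[{"patient_id": "P1", "date": "2016-08-01", "analyte": "uac", "value": 15.0}]
        )
        res = evaluate_qi(5, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 0.0

    def test_index_day_measurement_does_not_count_as_monitoring(self):
        ds = make_dataset(
            labs=[{"patient_id": "P1", "date": "2015-01-01", "analyte": "egfr", "value": 50.0}]
        )
        res = evaluate_qi(4, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 0.0

    def test_short_followup_drops_from_denominator(self):
        res = evaluate_qi(
            4, _cohorts(ckd=_single_ckd_member(followup_months=12.0)), make_dataset()
        )
        assert len(res.per_patient) == 0

    def test_qi6_requires_both_rf_and_bp(self):
        member = _single_ckd_member(g_stage="G3b")
        labs = [{"patient_id": "P1", "date": "2015-07-01", "analyte": "serum_creatinine", "value": 110.0}]
        only_rf = make_dataset(labs=labs)
        assert evaluate_qi(6, _cohorts(ckd=member), only_rf).achievement_rate == 0.0
        both = make_dataset(
            labs=labs,
            vitals=[{"patient_id": "P1", "date": "2015-09-01", "systolic_bp": 140.0}],
        )
        assert evaluate_qi(6, _cohorts(ckd=member), both).achievement_rate == 100.0


class TestTreatmentTargets:
    def test_latest_bp_decides_qi12(self):
        ds = make_dataset(
            vitals=[
                {"patient_id": "P1", "date": "2015-03-01", "systolic_bp": 150.0, "diastolic_bp": 95.0},
                {"patient_id": "P1", "date": "2016-03-01", "systolic_bp": 135.0, "diastolic_bp": 85.0},
            ]
        )
        res = evaluate_qi(12, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0

    def test_incomplete_reading_skipped_for_latest(self):
        ds = make_dataset(
            vitals=[
                {"patient_id": "P1", "date": "2015-03-01", "systolic_bp": 135.0, "diastolic_bp": 85.0},
                {"patient_id": "P1", "date": "2016-03-01", "systolic_bp": 150.0},
            ]
        )
        res = evaluate_qi(12, _cohorts(ckd=_single_ckd_member()), ds)
        assert res.achievement_rate == 100.0  # the complete 135/85 is the latest usable

    def test_qi13_uses_tighter_target_for_diabetics(self):
        ds = make_dataset(
            vitals=[{"patient_id": "P1", "date": "2016-01-01", "systolic_bp": 135.0, "diastolic_bp": 85.0}]
        )
        ckd = _single_ckd_member(has_diabetes=True)
        assert evaluate_qi(12, _cohorts(ckd=ckd), ds).achievement_rate == 100.0
        assert evaluate_qi(13, _cohorts(ckd=ckd), ds).achievement_rate == 0.0

    def test_bmi_from_weight_and_height(self):
        ds = make_dataset(
            vitals=[{"patient_id": "P1", "date": "2016-01-01", "weight": 60.0, "height": 165.0}]
        )
        res = evaluate_qi(14, _cohorts(ckd=_single_ckd_member()), ds)
        # 60 / 1.65^2 = 22.0 -> within [20, 25]
        assert res.achievement_rate == 100.0

    def test_no_measurement_means_not_in_denominator(self):
        res = evaluate_qi(12, _cohorts(ckd=_single_ckd_member()), make_dataset())
        assert len(res.per_patient) == 0


def test_unknown_qi_id_raises():
    with pytest.raises(ValueError):
        evaluate_qi(15, _cohorts(), make_dataset())


# ---------------------------------------------------------------------------
# whole-engine properties against an independent recount


def _pipeline(dataset):
    base = build_baseline(dataset)
    tl = label_conditions(dataset)
    ev = detect_ckd_all(dataset)
    rf = build_rf_cohort(base, tl)
    ckd = build_ckd_cohort(base, ev, tl)
    return {"rf": rf, "ckd": ckd}


def oracle_achieved(qi_id, member, dataset, cfg=QiConfig()):
    """Straight-line per-patient recount, independent of the engine."""
    pid = member["patient_id"]
    index = member["index_date"]
    labs = dataset.labs[dataset.labs["patient_id"] == pid]
    vit = dataset.vitals[dataset.vitals["patient_id"] == pid]
    rx = dataset.prescriptions[dataset.prescriptions["patient_id"] == pid]

    def lab_in(analytes, days, strict):
        for _, r in labs.iterrows():
            if r["analyte"] in analytes:
                lo = r["date"] > index if strict else r["date"] >= index
                if lo and r["date"] < index + pd.Timedelta(days=days):
                    return True
        return False

    def bp_in(days, strict):
        for _, r in vit.iterrows():
            if pd.notna(r["systolic_bp"]) or pd.notna(r["diastolic_bp"]):
                lo = r["date"] > index if strict else r["date"] >= index
                if lo and r["date"] < index + pd.Timedelta(days=days):
                    return True
        return False

    def rx_in(prefixes, days, exclude=()):
        win_end = index + pd.Timedelta(days=days)
        for _, r in rx.iterrows():
            code = str(r["atc_code"])
            if not code.startswith(tuple(prefixes)) or code.startswith(tuple(exclude)):
                continue
            if index <= r["date"] < win_end:
                return True
            if pd.notna(r["end_date"]) and r["date"] < win_end and r["end_date"] >= index:
                return True
        return False

    from ckdqi.qi import ALBUMINURIA, CBC, CHEMISTRY, MBD, RF_ANALYTES, SCR_EGFR

    if qi_id in (1, 2, 3):
        return lab_in(RF_ANALYTES, 548, strict=False)
    if qi_id == 4:
        return lab_in(SCR_EGFR, 548, strict=True)
    if qi_id == 5:
        return lab_in(ALBUMINURIA, 548, strict=True)
    if qi_id == 6:
        return lab_in(RF_ANALYTES, 548, True) and bp_in(548, True)
    if qi_id == 7:
        return (lab_in(RF_ANALYTES, 548, True) and bp_in(548, True)
                and lab_in(CBC, 548, True) and lab_in(CHEMISTRY, 548, True))
    if qi_id == 8:
        return (lab_in(RF_ANALYTES, 548, True) and bp_in(548, True)
                and lab_in(CBC, 548, True) and lab_in(CHEMISTRY, 548, True)
                and lab_in(MBD, 548, True))
    if qi_id == 9:
        return rx_in(cfg.raas_prefixes, 365)
    if qi_id == 10:
        return rx_in(cfg.statin_prefixes, 365)
    if qi_id == 11:
        return not rx_in(cfg.nsaid_prefixes, 365, exclude=cfg.nsaid_exclude_prefixes)
    if qi_id in (12, 13):
        complete = vit[(vit["systolic_bp"].notna()) & (vit["diastolic_bp"].notna())]
        after = complete[complete["date"] >= index].sort_values("date", kind="stable")
        if not len(after):
            return None
        last = after.iloc[-1]
        s, d = (140, 90) if qi_id == 12 else (130, 80)
        return bool(last["systolic_bp"] < s and last["diastolic_bp"] < d)
    if qi_id == 14:
        v = vit.copy()
        v["bmi_value"] = derive_bmi(v)
        after = v[(v["bmi_value"].notna()) & (v["date"] >= index)].sort_values("date", kind="stable")
        if not len(after):
            return None
        return bool(20.0 <= after.iloc[-1]["bmi_value"] <= 25.0)
    raise AssertionError(qi_id)


def test_rates_match_per_patient_recount(small_emr):
    dataset, _ = small_emr
    cohorts = _pipeline(dataset)
    results, summary = evaluate_all(cohorts, dataset)
    for res in results:
        for _, member in res.per_patient.merge(
            cohorts["rf" if res.category == "assessment" else "ckd"],
            on="patient_id", suffixes=("", "_c"),
        ).iterrows():
            expected = oracle_achieved(res.qi_id, member, dataset)
            assert expected is not None
            assert bool(member["achieved"]) == expected, (res.qi_id, member["patient_id"])


def test_summary_invariants(small_emr):
    dataset, _ = small_emr
    cohorts = _pipeline(dataset)
    results, summary = evaluate_all(cohorts, dataset)
    assert len(summary) == 14
    rates = summary["achievement_rate"].dropna()
    assert ((rates >= 0) & (rates <= 100)).all()
    for res in results:
        n_num = int(res.per_patient["achieved"].sum())
        assert 0 <= n_num <= len(res.per_patient)
    # QI 13 denominator is the diabetic subset of QI 12's
    d12 = set(results[11].per_patient["patient_id"])
    d13 = set(results[12].per_patient["patient_id"])
    diabetics = set(
        cohorts["ckd"].loc[cohorts["ckd"]["has_diabetes"], "patient_id"]
    )
    assert d13 == d12 & diabetics


def test_denominator_monotone_in_followup():
    # extending follow-up (later last contact) can only add members
    member = _single_ckd_member(followup_months=17.0)
    res_short = evaluate_qi(4, _cohorts(ckd=member), make_dataset())
    member_long = _single_ckd_member(followup_months=19.0)
    res_long = evaluate_qi(4, _cohorts(ckd=member_long), make_dataset())
    assert len(res_short.per_patient) == 0
    assert len(res_long.per_patient) == 1
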