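"""CKD-EPI evaluation, KDIGO staging, and the two-measurement case rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdqi.renal import (
    DetectionThresholds,
    ckd_epi_egfr,
    detect_ckd,
    detect_ckd_all,
    rf_measurements,
    stage_a,
    stage_g,
)


def reference_ckd_epi(scr_umol, age, female):
    """Independent single-expression evaluation of the published equation."""
    scr = scr_umol / 88.42
    k = 0.7 if female else 0.9
    a = -0.329 if female else -0.411
    return (
        141.0
        * min(scr / k, 1.0) ** a
        * max(scr / k, 1.0) ** -1.209
        * 0.993**age
        * (1.018 if female else 1.0)
    )


class TestCkdEpi:
    def test_reference_values(self):
        assert ckd_epi_egfr(61.9, 60, "female") == pytest.approx(94.2, abs=0.05)
        val = ckd_epi_egfr(150.0, 70, "male")
        assert val == pytest.approx(40.1, abs=0.05)
        assert stage_g(val) == "G3b"

    def test_kappa_boundary_identity(self):
        # at Scr = kappa mg/dL both power terms are 1: eGFR = 141 * 0.993^age
        for age in (20, 50, 85):
            assert ckd_epi_egfr(0.9 * 88.42, age, "male") == pytest.approx(
                141.0 * 0.993**age, rel=1e-12
            )

    def test_matches_independent_expression_on_grid(self):
        scr = np.linspace(30.0, 900.0, 250)
        for age in (20, 45, 70, 95):
            for sex in ("female", "male"):
                ours = ckd_epi_egfr(scr, age, sex)
                ref = [reference_ckd_epi(s, age, sex == "female") for s in scr]
                np.testing.assert_allclose(ours, ref, rtol=1e-9)

    def test_other_gender_yields_missing(self):
        assert np.isnan(ckd_epi_egfr(100.0, 60, "other"))

    def test_monotone_in_creatinine(self):
        scr = np.linspace(40, 600, 300)
        egfr = ckd_epi_egfr(scr, 65, "female")
        assert (np.diff(egfr) < 0).all()
        stages = stage_g(egfr)
        order = {"G1": 0, "G2": 1, "G3a": 2, "G3b": 3, "G4": 4, "G5": 5}
        ranks = np.array([order[s] for s in stages])
        assert (np.diff(ranks) >= 0).all()

    def test_rejects_nonpositive_creatinine(self):
        with pytest.raises(ValueError):
            ckd_epi_egfr(0.0, 60, "female")


@pytest.mark.parametrize(
    "egfr, expected",
    [(90.0, "G1"), (60.0, "G2"), (59.99, "G3a"), (45.0, "G3a"), (44.99, "G3b"),
     (30.0, "G3b"), (29.99, "G4"), (15.0, "G4"), (14.9, "G5"), (0.0, "G5")],
)
def test_stage_g_boundaries(egfr, expected):
    assert stage_g(egfr) == expected


@pytest.mark.parametrize(
    "acr, expected",
    [(0.0, "A1"), (2.99, "A1"), (3.0, "A2"), (30.0, "A2"), (30.01, "A3")],
)
def test_stage_a_boundaries(acr, expected):
    assert stage_a(acr) == expected


def test_stages_reject_negative_input():
    with pytest.raises(ValueError):
        stage_g(-1.0)
    with pytest.raises(ValueError):
        stage_a(-0.1)


# ---------------------------------------------------------------------------
# case detection


def brute_force_detect(series, gap_days=90):
    """Enumerate all measurement pairs per criterion; independent oracle."""
    dates = pd.to_datetime(series["date"]).to_list()
    best = {}
    for crit, col, pred in (
        ("egfr", "egfr", lambda v: v < 60),
        ("uac", "uac", lambda v: v >= 20),
        ("acr", "acr", lambda v: v >= 3),
    ):
        vals = pd.to_numeric(series.get(col), errors="coerce").to_list()
        qual = [d for d, v in zip(dates, vals) if v == v and pred(v)]
        pair_dates = [
            max(a, b)
            for i, a in enumerate(qual)
            for b in qual[i + 1 :]
            if abs((a - b).days) >= gap_days
        ]
        if pair_dates:
            best[crit] = min(pair_dates)
    if not best:
        return False, None, None
    crit = min(best, key=lambda c: (best[c], ("egfr", "uac", "acr").index(c)))
    return True, best[crit], crit


def _series(rows):
    return pd.DataFrame(rows, columns=["date", "egfr", "acr", "uac"])


class TestDetectCkd:
    def test_single_abnormal_value_is_not_confirmed(self):
        ev = detect_ckd(_series([{"date": "2014-01-10", "egfr": 45.0}]))
        assert not ev.ckd_confirmed
        assert ev.evidence_date is None

    def test_two_low_egfr_three_months_apart_confirm(self):
        ev = detect_ckd(
            _series(
                [
                    {"date": "2014-01-10", "egfr": 55.0},
                    {"date": "2014-04-15", "egfr": 52.0},
                ]
            )
        )
        assert ev.ckd_confirmed
        assert ev.evidence_date == pd.Timestamp("2014-04-15")
        assert ev.criterion == "egfr"
        assert ev.g_stage_at_inclusion == "G3a"

    def test_short_gap_does_not_confirm(self):
        ev = detect_ckd(
            _series(
                [
                    {"date": "2014-01-10", "egfr": 55.0},
                    {"date": "2014-02-01", "egfr": 58.0},
                    {"date": "2014-06-01", "egfr": 70.0},
                    {"date": "2015-06-01", "egfr": 72.0},
                ]
            )
        )
        assert not ev.ckd_confirmed

    def test_intervening_normal_values_do_not_reset(self):
        ev = detect_ckd(
            _series(
                [
                    {"date": "2014-01-10", "egfr": 55.0},
                    {"date": "2014-03-01", "egfr": 75.0},
                    {"date": "2014-09-01", "egfr": 58.0},
                ]
            )
        )
        assert ev.ckd_confirmed
        assert ev.evidence_date == pd.Timestamp("2014-09-01")

    def test_ever_g5_flag(self):
        ev = detect_ckd(
            _series(
                [
                    {"date": "2014-01-10", "egfr": 12.0},
                    {"date": "2014-06-01", "egfr": 55.0},
                ]
            )
        )
        assert ev.ever_g5

    def test_empty_series(self):
        ev = detect_ckd(_series([]))
        assert not ev.ckd_confirmed

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_pair_enumeration_oracle(self, data):
        n = data.draw(st.integers(0, 20))
        days = data.draw(
            st.lists(st.integers(0, 2500), min_size=n, max_size=n)
        )
        rows = []
        for d in days:
            rows.append(
                {
                    "date": pd.Timestamp("2013-01-01") + pd.Timedelta(days=d),
                    "egfr": data.draw(
                        st.one_of(st.none(), st.floats(5, 120, allow_nan=False))
                    ),
                    "acr": data.draw(
                        st.one_of(st.none(), st.floats(0.1, 60, allow_nan=False))
                    ),
                    "uac": data.draw(
                        st.one_of(st.none(), st.floats(0.5, 300, allow_nan=False))
                    ),
                }
            )
        series = _series(rows)
        ev = detect_ckd(series)
        confirmed, date, crit = brute_force_detect(series)
        assert ev.ckd_confirmed == confirmed
        assert ev.evidence_date == date
        assert ev.criterion == crit

    @given(data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adding_measurements_never_unconfirms(self, data):
        days = data.draw(st.lists(st.integers(0, 2000), min_size=2, max_size=12))
        egfrs = data.draw(
            st.lists(st.floats(10, 110, allow_nan=False), min_size=len(days), max_size=len(days))
        )
        rows = [
            {"date": pd.Timestamp("2013-01-01") + pd.Timedelta(days=d), "egfr": v}
            for d, v in zip(days, egfrs)
        ]
        series = _series(rows)
        ev_full = detect_ckd(series)
        k = data.draw(st.integers(1, len(rows)))
        ev_sub = detect_ckd(_series(rows[:k]))
        if ev_sub.ckd_confirmed:
            assert ev_full.ckd_confirmed
            assert ev_full.evidence_date <= ev_sub.evidence_date


def test_reported_egfr_takes_precedence_over_creatinine(tiny_dataset):
    labs = tiny_dataset.labs.copy()
    # same-day pair: reported eGFR 70 should win over creatinine-derived value
    extra = pd.DataFrame(
        [
            {"patient_id": "P1", "date": pd.Timestamp("2014-02-01"),
             "analyte": "egfr", "value": 70.0, "unit": "mL/min/1.73m2"},
        ]
    )
    tiny_dataset.labs = pd.concat([labs, extra], ignore_index=True)
    series = rf_measurements(tiny_dataset)
    row = series[(series["patient_id"] == "P1")].iloc[0]
    assert row["egfr"] == 70.0


def test_detect_ckd_all_covers_every_patient(tiny_dataset):
    ev = detect_ckd_all(tiny_dataset)
    assert set(ev["patient_id"]) == set(tiny_dataset.patients["patient_id"])
    p2 = ev.set_index("patient_id").loc["P2"]
    assert p2["ckd_confirmed"]
    assert p2["criterion"] == "egfr"
    assert p2["evidence_date"] == pd.Timestamp("2014-08-01")


def test_configurable_gap(tiny_dataset):
    ev = detect_ckd(
        _series(
            [
                {"date": "2014-01-01", "egfr": 50.0},
                {"date": "2014-02-15", "egfr": 52.0},
            ]
        ),
        thresholds=DetectionThresholds(min_gap_days=30),
    )
    assert ev.ckd_confirmed
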