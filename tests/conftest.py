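import numpy as np
import pandas as pd
import pytest

from ckdqi.datamodel import CANONICAL_UNITS, EmrDataset


def make_dataset(
    patients=None,
    gps=None,
    encounters=(),
    prescriptions=(),
    labs=(),
    vitals=(),
    window=("2013-01-01", "2019-12-31"),
) -> EmrDataset:
    """Build a small in-memory dataset from row dicts with defaults filled."""
    if gps is None:
        gps = [{"gp_id": "G1", "gender": "female", "birth_year": 1970.0, "urban_location": True}]
    if patients is None:
        patients = [
            {"patient_id": "P1", "gp_id": "G1", "gender": "female", "birth_year": 1950.0},
            {"patient_id": "P2", "gp_id": "G1", "gender": "male", "birth_year": 1940.0},
            {"patient_id": "P3", "gp_id": "G1", "gender": "female", "birth_year": 1935.0},
        ]

    def frame(rows, cols, defaults=None):
        df = pd.DataFrame(list(rows), columns=cols)
        for c in cols:
            if c not in df:
                df[c] = np.nan
        if "date" in df:
            df["date"] = pd.to_datetime(df["date"])
        if "end_date" in df:
            df["end_date"] = pd.to_datetime(df["end_date"])
        return df

    labs_df = frame(labs, ["patient_id", "date", "analyte", "value", "unit"])
    if len(labs_df):
        labs_df["unit"] = labs_df["unit"].fillna(labs_df["analyte"].map(CANONICAL_UNITS))
    return EmrDataset(
        patients=pd.DataFrame(patients),
        gps=pd.DataFrame(gps),
        encounters=frame(encounters, ["patient_id", "date", "icpc2_code"]),
        prescriptions=frame(prescriptions, ["patient_id", "date", "atc_code", "end_date"]),
        labs=labs_df,
        vitals=frame(
            vitals,
            ["patient_id", "date", "systolic_bp", "diastolic_bp", "weight", "height", "bmi"],
        ),
        study_window=(pd.Timestamp(window[0]), pd.Timestamp(window[1])),
    ).validate()


@pytest.fixture
def tiny_dataset():
    """Three patients, one GP, a handful of events of every type."""
    return make_dataset(
        encounters=[
            {"patient_id": "P1", "date": "2014-02-01", "icpc2_code": "T90"},
            {"patient_id": "P2", "date": "2014-03-01", "icpc2_code": None},
            {"patient_id": "P3", "date": "2015-01-15", "icpc2_code": "K86"},
        ],
        prescriptions=[
            {"patient_id": "P1", "date": "2014-02-01", "atc_code": "A10BA02"},
            {"patient_id": "P3", "date": "2015-02-01", "atc_code": "C09AA02"},
        ],
        labs=[
            {"patient_id": "P1", "date": "2014-02-01", "analyte": "serum_creatinine", "value": 95.0},
            {"patient_id": "P2", "date": "2014-03-01", "analyte": "egfr", "value": 55.0},
            {"patient_id": "P2", "date": "2014-08-01", "analyte": "egfr", "value": 52.0},
            {"patient_id": "P3", "date": "2015-01-15", "analyte": "acr", "value": 4.0},
        ],
        vitals=[
            {"patient_id": "P1", "date": "2014-02-01", "systolic_bp": 135.0, "diastolic_bp": 82.0},
            {"patient_id": "P3", "date": "2015-01-15", "systolic_bp": 150.0, "diastolic_bp": 95.0},
        ],
    )


@pytest.fixture
def small_emr():
    """A modest synthetic dataset shared across integration-style tests."""
    from ckdqi.simulate import SimulationConfig, generate_emr

    cfg = SimulationConfig(n_gps=12, patients_per_gp_mean=30, seed=11)
    dataset, truth = generate_emr(cfg)
    return dataset, truth
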