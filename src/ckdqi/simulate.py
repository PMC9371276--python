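"""Synthetic EMR generation with known ground truth.

``generate_emr`` builds a fully linked, bit-reproducible EMR dataset with
the statistical structure the analysis assumes: patients clustered within
GPs, per-GP random intercepts on care propensities (test ordering,
prescribing, blood-pressure control), longitudinal serum-creatinine /
albuminuria trajectories, condition-defining codes, prescriptions, and
vitals over a 2013-2019-style window. The returned
:class:`SyntheticTruth` records the realised GP intercepts and the
config, enabling parameter-recovery tests: the latent-scale ICC implied by
an intercept SD sigma_b is sigma_b^2/(sigma_b^2 + pi^2/3), and the
large-sample range odds ratio is exp(3.2897 * sigma_b) (the central-90%
normal range).

``generate_clustered_binary`` is a direct harness for the variation
models: clustered Bernoulli outcomes with known fixed effects and
intercept SD, no EMR plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.special import expit

from .datamodel import CANONICAL_UNITS, EmrDataset
from .renal import UMOL_PER_MGDL

#: z_{0.95} - z_{0.05} of the standard normal
NORMAL_CENTRAL_90_RANGE = 3.2897


class TrajectoryConfig(BaseModel):
    """True eGFR trajectory: linear age effect, annual decline, lab noise."""

    egfr_at_40: float = 95.0          # mean true eGFR at age 40, mL/min/1.73m2
    egfr_age_slope: float = -0.85     # per year of age at entry
    egfr_sd: float = 13.0             # between-patient SD at entry
    annual_decline: float = 1.6       # mean within-patient decline per year
    measurement_cv: float = 0.06      # multiplicative lab noise on creatinine
    reported_egfr_fraction: float = 0.3  # labs reported as eGFR vs creatinine


class SimulationConfig(BaseModel):
    """Study-condition parameters of the synthetic EMR generator."""

    n_gps: int = 60
    patients_per_gp_mean: float = 80.0
    patients_per_gp_dispersion: float = 8.0   # negative-binomial shape
    study_window: tuple[str, str] = ("2013-01-01", "2019-12-31")
    visit_rate_per_year: float = 4.0

    #: GP intercept SD per simulated behaviour (log-odds scale)
    sigma_b: dict[str, float] = Field(
        default_factory=lambda: {
            "rf_test": 1.1,
            "alb_test": 1.1,
            "raas_rx": 0.5,
            "statin_rx": 0.45,
            "nsaid_rx": 0.5,
            "bp_control": 0.45,
        }
    )
    #: baseline log-odds of each behaviour (per visit or per patient)
    baseline_log_odds: dict[str, float] = Field(
        default_factory=lambda: {
            "rf_test": -1.55,     # per visit
            "alb_test": -3.8,     # per visit
            "raas_rx": 1.2,       # per patient-year, if indicated
            "statin_rx": 0.1,     # per patient-year, age 50+
            "nsaid_rx": -2.0,     # per patient-year
            "bp_control": 0.5,    # per patient
        }
    )
    #: fixed-effect log-odds added to behaviour propensities
    fixed_effect_log_odds: dict[str, float] = Field(
        default_factory=lambda: {
            "rf_test_male": 0.15,
            "rf_test_age_per_decade": 0.12,
            "rf_test_condition": 0.35,
            "alb_test_diabetes": 0.6,
            "alb_test_male": 0.2,
        }
    )
    #: age-50 condition prevalences; logistic in age around 50
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {"diabetes": 0.10, "hypertension": 0.28, "ecvd": 0.08}
    )
    prevalence_age_slope: float = 0.045  # log-odds per year of age
    age_mean: float = 62.0
    age_sd: float = 16.0
    female_fraction: float = 0.52
    trajectory: TrajectoryConfig = Field(default_factory=TrajectoryConfig)
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests."""

    config: SimulationConfig
    gp_intercepts: dict[str, np.ndarray]  # behaviour -> per-GP intercepts
    theoretical_icc: dict[str, float] = field(default_factory=dict)
    theoretical_ror: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.config.sigma_b.items():
            self.theoretical_icc[name] = sd**2 / (sd**2 + np.pi**2 / 3.0)
            self.theoretical_ror[name] = float(np.exp(NORMAL_CENTRAL_90_RANGE * sd))

    def to_dict(self) -> dict:
        return {
            "config": self.config.model_dump(),
            "gp_intercepts": {k: v.tolist() for k, v in self.gp_intercepts.items()},
            "theoretical_icc": self.theoretical_icc,
            "theoretical_ror": self.theoretical_ror,
        }


def _egfr_to_scr_umol(egfr, age, female):
    """Invert the CKD-EPI equation (exact two-branch inverse)."""
    base = 141.0 * 0.993**age * np.where(female, 1.018, 1.0)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = np.where(
        egfr <= base, (egfr / base) ** (-1.0 / 1.209), (egfr / base) ** (1.0 / alpha)
    )
    return ratio * kappa * UMOL_PER_MGDL


def generate_emr(config: SimulationConfig | None = None, seed: int | None = None):
    """Draw one synthetic EMR dataset; returns ``(EmrDataset, SyntheticTruth)``."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    if any(sd < 0 for sd in cfg.sigma_b.values()):
        raise ValueError("sigma_b values must be non-negative")
    if not 0 <= cfg.female_fraction <= 1:
        raise ValueError("female_fraction must be a probability")
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.study_window[0])
    end = pd.Timestamp(cfg.study_window[1])
    window_days = (end - start).days

    # ------------------------------------------------------------------ GPs
    n_gps = cfg.n_gps
    gp_ids = np.array([f"GP{i:04d}" for i in range(n_gps)])
    gp_gender = rng.choice(
        ["female", "male", "unknown"], size=n_gps, p=[0.44, 0.548, 0.012]
    )
    gp_birth = 2013 - np.clip(rng.normal(49, 9, n_gps), 32, 70).round()
    gp_urban = rng.random(n_gps) < 0.747
    gps = pd.DataFrame(
        {
            "gp_id": gp_ids,
            "gender": gp_gender,
            "birth_year": gp_birth,
            "urban_location": gp_urban,
        }
    )
    intercepts = {
        name: rng.normal(0.0, sd, n_gps) for name, sd in cfg.sigma_b.items()
    }
    truth = SyntheticTruth(config=cfg, gp_intercepts=intercepts)

    # ------------------------------------------------------------- patients
    n_per_gp = rng.negative_binomial(
        cfg.patients_per_gp_dispersion,
        cfg.patients_per_gp_dispersion
        / (cfg.patients_per_gp_dispersion + cfg.patients_per_gp_mean),
        n_gps,
    )
    n_per_gp = np.maximum(n_per_gp, 1)
    n_pat = int(n_per_gp.sum())
    pat_gp = np.repeat(np.arange(n_gps), n_per_gp)
    pat_ids = np.array([f"P{i:06d}" for i in range(n_pat)])
    female = rng.random(n_pat) < cfg.female_fraction
    gender = np.where(female, "female", "male").astype(object)
    # a handful of patients of other gender, as real registries carry
    other_idx = rng.choice(n_pat, size=max(1, n_pat // 2000), replace=False)
    gender[other_idx] = "other"
    age_entry = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n_pat), 18, 97)
    entry_offset = rng.uniform(0, max(window_days - 730, 1), n_pat).astype(int)
    entry = start + pd.to_timedelta(entry_offset, unit="D")
    birth_year = entry.year - age_entry.round().astype(int)
    patients = pd.DataFrame(
        {
            "patient_id": pat_ids,
            "gp_id": gp_ids[pat_gp],
            "gender": gender,
            "birth_year": birth_year.astype(float),
        }
    )

    # conditions: prevalence logistic in age; onset uniform in [entry, end-30d]
    cond_onset = {}
    for cond, prev in cfg.prevalence.items():
        lo = np.log(prev / (1 - prev)) + cfg.prevalence_age_slope * (age_entry - 50)
        has = rng.random(n_pat) < expit(lo)
        onset_span = np.maximum((end - entry).days.to_numpy() - 30, 1)
        onset = entry + pd.to_timedelta(
            (rng.random(n_pat) * onset_span).astype(int), unit="D"
        )
        cond_onset[cond] = pd.Series(onset).where(pd.Series(has), pd.NaT)

    # --------------------------------------------------------------- visits
    span_years = (end - entry).days.to_numpy() / 365.25
    n_visits = rng.poisson(cfg.visit_rate_per_year * span_years)
    n_visits = np.maximum(n_visits, 1)
    v_pat = np.repeat(np.arange(n_pat), n_visits)
    v_frac = rng.random(len(v_pat))
    v_span = np.repeat((end - entry).days.to_numpy(), n_visits)
    v_date = np.repeat(entry.to_numpy(), n_visits) + (
        (v_frac * v_span).astype(int) * np.timedelta64(1, "D")
    )
    visits = pd.DataFrame(
        {"pat": v_pat, "date": pd.to_datetime(v_date), "gp": pat_gp[v_pat]}
    ).sort_values(["pat", "date"], kind="stable", ignore_index=True)
    v_pat = visits["pat"].to_numpy()
    v_gp = visits["gp"].to_numpy()
    v_date = visits["date"]
    n_vis = len(visits)
    v_age = v_date.dt.year.to_numpy() - birth_year.to_numpy()[v_pat]
    v_female = female[v_pat]

    fe = cfg.fixed_effect_log_odds
    any_cond = np.zeros(n_pat, dtype=bool)
    for cond in cond_onset:
        any_cond |= cond_onset[cond].notna().to_numpy()

    # ----------------------------------------------------------- encounters
    encounters = pd.DataFrame(
        {
            "patient_id": pat_ids[v_pat],
            "date": v_date,
            "icpc2_code": pd.Series([None] * n_vis, dtype=object),
        }
    )
    cond_code = {"diabetes": "T90", "hypertension": "K86", "ecvd": "K74"}
    extra_enc = []
    for cond, code in cond_code.items():
        onset = cond_onset[cond]
        m = onset.notna().to_numpy()
        extra_enc.append(
            pd.DataFrame(
                {
                    "patient_id": pat_ids[m],
                    "date": pd.to_datetime(onset[m].to_numpy()),
                    "icpc2_code": code,
                }
            )
        )
    encounters = pd.concat([encounters, *extra_enc], ignore_index=True)

    # ------------------------------------------------------------ RF labs
    traj = cfg.trajectory
    egfr_entry = (
        traj.egfr_at_40
        + traj.egfr_age_slope * (age_entry - 40.0)
        + rng.normal(0, traj.egfr_sd, n_pat)
    )
    decline = np.maximum(rng.normal(traj.annual_decline, 0.8, n_pat), 0.0)
    years_since_entry = (
        (v_date.to_numpy() - np.repeat(entry.to_numpy(), n_visits)).astype(
            "timedelta64[D]"
        ).astype(float)
        / 365.25
    )
    v_egfr_true = np.clip(
        egfr_entry[v_pat] - decline[v_pat] * years_since_entry, 4.0, 140.0
    )

    p_rf = expit(
        cfg.baseline_log_odds["rf_test"]
        + fe.get("rf_test_male", 0.0) * (~v_female)
        + fe.get("rf_test_age_per_decade", 0.0) * (v_age - 60) / 10.0
        + fe.get("rf_test_condition", 0.0) * any_cond[v_pat]
        + intercepts["rf_test"][v_gp]
    )
    rf_tested = rng.random(n_vis) < p_rf
    scr_noise = rng.lognormal(0.0, traj.measurement_cv, n_vis)
    scr_meas = (
        _egfr_to_scr_umol(v_egfr_true, v_age, v_female) * scr_noise
    )
    as_egfr = rng.random(n_vis) < traj.reported_egfr_fraction
    rf_rows = []
    m = rf_tested & ~as_egfr
    rf_rows.append(
        pd.DataFrame(
            {
                "patient_id": pat_ids[v_pat[m]],
                "date": v_date[m],
                "analyte": "serum_creatinine",
                "value": np.round(scr_meas[m], 1),
            }
        )
    )
    m = rf_tested & as_egfr
    egfr_meas = np.clip(v_egfr_true * rng.lognormal(0, traj.measurement_cv, n_vis), 3, 150)
    rf_rows.append(
        pd.DataFrame(
            {
                "patient_id": pat_ids[v_pat[m]],
                "date": v_date[m],
                "analyte": "egfr",
                "value": np.round(egfr_meas[m], 1),
            }
        )
    )

    # albuminuria: tested rarely; level elevated in diabetics / low eGFR
    diab = cond_onset["diabetes"].notna().to_numpy()
    p_alb = expit(
        cfg.baseline_log_odds["alb_test"]
        + fe.get("alb_test_diabetes", 0.0) * diab[v_pat]
        + fe.get("alb_test_male", 0.0) * (~v_female)
        + intercepts["alb_test"][v_gp]
    )
    alb_tested = rng.random(n_vis) < p_alb
    log_acr = (
        np.log(2.0)
        + 1.0 * diab[v_pat]
        + 0.03 * np.maximum(60.0 - v_egfr_true, 0.0)
        + rng.normal(0, 1.0, n_vis)
    )
    acr_val = np.exp(log_acr)
    as_acr = rng.random(n_vis) < 0.5
    m = alb_tested & as_acr
    rf_rows.append(
        pd.DataFrame(
            {
                "patient_id": pat_ids[v_pat[m]],
                "date": v_date[m],
                "analyte": "acr",
                "value": np.round(acr_val[m], 2),
            }
        )
    )
    m = alb_tested & ~as_acr
    rf_rows.append(
        pd.DataFrame(
            {
                "patient_id": pat_ids[v_pat[m]],
                "date": v_date[m],
                "analyte": "uac",
                # UAC in mg/L, roughly ACR (mg/mmol) * 8 for spot urine
                "value": np.round(acr_val[m] * 8.0, 1),
            }
        )
    )

    # supporting labs drawn per visit with fixed order probabilities
    other_labs = {
        "hemoglobin": (0.25, 132.0, 14.0, 0),
        "sodium": (0.20, 141.0, 2.5, 0),
        "potassium": (0.20, 4.3, 0.4, 1),
        "urea": (0.05, 9.5, 3.0, 1),
        "alkaline_phosphatase": (0.10, 78.0, 25.0, 0),
        "calcium": (0.05, 2.36, 0.12, 2),
        "phosphate": (0.012, 1.1, 0.18, 2),
        "parathyroid_hormone": (0.006, 65.0, 30.0, 1),
        "hba1c": (0.08, 5.6, 0.45, 1),
        "ldl": (0.08, 2.7, 0.9, 2),
        "total_cholesterol": (0.09, 4.9, 1.0, 2),
    }
    for analyte, (p, mean, sd, dec) in other_labs.items():
        m = rng.random(n_vis) < p
        vals = np.maximum(rng.normal(mean, sd, n_vis), mean / 10)
        if analyte == "hba1c":  # diabetics run higher
            vals = vals + 1.4 * diab[v_pat]
        rf_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pat_ids[v_pat[m]],
                    "date": v_date[m],
                    "analyte": analyte,
                    "value": np.round(vals[m], dec),
                }
            )
        )
    labs = pd.concat(rf_rows, ignore_index=True)
    labs["value"] = labs["value"].clip(lower=0.01)
    labs["unit"] = labs["analyte"].map(CANONICAL_UNITS)

    # --------------------------------------------------------------- vitals
    hyp = cond_onset["hypertension"].notna().to_numpy()
    p_controlled = expit(
        cfg.baseline_log_odds["bp_control"]
        + 0.25 * (~female)
        + intercepts["bp_control"][pat_gp]
    )
    controlled = rng.random(n_pat) < p_controlled
    bp_measured = rng.random(n_vis) < 0.6
    sys_mean = np.where(controlled[v_pat], 126.0, 150.0) + 4.0 * hyp[v_pat]
    dia_mean = np.where(controlled[v_pat], 75.0, 88.0)
    sys_v = rng.normal(sys_mean, 8.0)
    dia_v = rng.normal(dia_mean, 7.0)
    bmi_base = np.clip(rng.normal(27.0, 4.5, n_pat), 16, 55)
    bmi_measured = rng.random(n_vis) < 0.25
    bmi_v = bmi_base[v_pat] + rng.normal(0, 0.7, n_vis)
    as_bmi = rng.random(n_vis) < 0.5
    height = np.clip(rng.normal(np.where(female, 164, 177), 7.0), 140, 210)
    vit = pd.DataFrame(
        {
            "patient_id": pat_ids[v_pat],
            "date": v_date,
            "systolic_bp": np.where(bp_measured, np.round(sys_v), np.nan),
            "diastolic_bp": np.where(bp_measured, np.round(dia_v), np.nan),
            "weight": np.where(
                bmi_measured & ~as_bmi,
                np.round(bmi_v * (height[v_pat] / 100.0) ** 2, 1),
                np.nan,
            ),
            "height": np.where(bmi_measured & ~as_bmi, np.round(height[v_pat]), np.nan),
            "bmi": np.where(bmi_measured & as_bmi, np.round(bmi_v, 1), np.nan),
        }
    )
    vitals = vit.loc[
        vit[["systolic_bp", "diastolic_bp", "weight", "height", "bmi"]].notna().any(axis=1)
    ].reset_index(drop=True)

    # --------------------------------------------------------- prescriptions
    rx_rows = []
    yearly = np.maximum(np.ceil(span_years).astype(int), 1)

    def _yearly_prescriptions(indicated, logit_p, atc_choices):
        rows = []
        idx = np.flatnonzero(indicated)
        for i in idx:
            p = expit(logit_p[i])
            k = rng.binomial(yearly[i], p)
            if k == 0:
                continue
            offs = rng.integers(0, max((end - entry[i]).days, 1), k)
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pat_ids[i],
                        "date": entry[i] + pd.to_timedelta(offs, unit="D"),
                        "atc_code": rng.choice(atc_choices, k),
                    }
                )
            )
        return rows

    raas_logit = cfg.baseline_log_odds["raas_rx"] + intercepts["raas_rx"][pat_gp]
    # indicated for hypertension, diabetes, or reduced renal function
    raas_ind = hyp | diab | (egfr_entry - decline * span_years < 60.0)
    rx_rows += _yearly_prescriptions(raas_ind, raas_logit, ["C09AA02", "C09CA01", "C09AA05"])
    statin_logit = (
        cfg.baseline_log_odds["statin_rx"]
        + 0.2 * (~female)
        + intercepts["statin_rx"][pat_gp]
    )
    rx_rows += _yearly_prescriptions(
        age_entry >= 50, statin_logit, ["C10AA01", "C10AA05", "C10BA02"]
    )
    nsaid_logit = cfg.baseline_log_odds["nsaid_rx"] + intercepts["nsaid_rx"][pat_gp]
    rx_rows += _yearly_prescriptions(
        np.ones(n_pat, dtype=bool), nsaid_logit, ["M01AB05", "M01AE01", "M01AH01"]
    )
    ecvd = cond_onset["ecvd"].notna().to_numpy()
    rx_rows += _yearly_prescriptions(ecvd, np.full(n_pat, 0.5), ["B01AC06"])
    diab_rx = diab & (rng.random(n_pat) < 0.7)
    rx_rows += _yearly_prescriptions(
        diab_rx, np.full(n_pat, 0.9), ["A10BA02", "A10AB01"]
    )
    if rx_rows:
        prescriptions = pd.concat(rx_rows, ignore_index=True)
    else:
        prescriptions = pd.DataFrame(columns=["patient_id", "date", "atc_code"])
    prescriptions["end_date"] = pd.NaT
    prescriptions = prescriptions.sort_values(
        ["patient_id", "date"], kind="stable", ignore_index=True
    )

    dataset = EmrDataset(
        patients=patients,
        gps=gps,
        encounters=encounters.sort_values(
            ["patient_id", "date"], kind="stable", ignore_index=True
        ),
        prescriptions=prescriptions,
        labs=labs.sort_values(["patient_id", "date"], kind="stable", ignore_index=True),
        vitals=vitals,
        study_window=(start, end),
    ).validate()
    return dataset, truth


def generate_clustered_binary(
    n_clusters: int,
    n_per_cluster: int,
    sigma_b: float,
    beta: dict[str, float] | None = None,
    seed: int = 0,
    intercept: float = 0.0,
):
    """Clustered Bernoulli outcomes with known truth.

    ``beta`` maps covariate names to log-odds coefficients; covariates are
    iid Bernoulli(0.5) (name ending ``_num``: standard normal). Returns
    ``(DataFrame, truth_dict)`` where the frame has columns ``y``,
    ``gp_id`` and the covariates.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, n_clusters)
    g = np.repeat(np.arange(n_clusters), n_per_cluster)
    eta = intercept + b[g]
    data = {"gp_id": g}
    beta = beta or {}
    for name, coef in beta.items():
        x = (
            rng.normal(size=len(g))
            if name.endswith("_num")
            else rng.binomial(1, 0.5, len(g)).astype(float)
        )
        data[name] = x
        eta = eta + coef * x
    data["y"] = rng.binomial(1, expit(eta)).astype(float)
    df = pd.DataFrame(data)
    truth = {
        "sigma_b": sigma_b,
        "intercept": intercept,
        "beta": dict(beta),
        "cluster_intercepts": b,
        "theoretical_icc": sigma_b**2 / (sigma_b**2 + np.pi**2 / 3.0),
        "theoretical_ror": float(np.exp(NORMAL_CENTRAL_90_RANGE * sigma_b)),
    }
    return df, truth
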