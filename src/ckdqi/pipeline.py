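"""End-to-end pipeline: tables in, result surfaces out.

``run_pipeline`` composes ingestion (or synthesis), CKD detection,
condition labelling, cohort construction, QI evaluation, and the
variation models, and writes a reproducible output bundle:

* ``cohort_characteristics.csv`` — descriptive summaries per cohort
  (counts/percentages, median/IQR, latest lab and vital values; pairwise
  deletion: each variable summarised over the patients carrying it);
* ``qi_summary.csv`` — per-QI denominator size, achievement rate, and
  null-model rOR / ICC;
* ``forest_qi<N>.csv`` — full-model odds ratios with 95% CIs per QI;
* ``model_qi<N>.json`` — full and null model parameter summaries;
* ``per_patient_qi<N>.csv`` — the per-patient achievement flags;
* ``manifest.json`` — config, seed, row counts, and stage log.

Printed precision follows reporting practice for this analysis type:
percentages and rates to 1 decimal, OR and ICC to 2, rOR to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import build_baseline, build_ckd_cohort, build_rf_cohort
from .conditions import CONDITIONS, label_conditions, load_rule_set
from .datamodel import EmrDataset, ages_at, derive_bmi
from .io import IngestionConfig, read_emr_tables, write_table
from .qi import QiConfig, evaluate_all
from .renal import detect_ckd_all
from .simulate import SimulationConfig, generate_emr
from .variation import FitError, analyse_qi_variation

PATIENT_AGE_BREAKS = {"rf_assessment": (40, 60, 80), "ckd_care": (65, 80)}
GP_AGE_BREAKS = (45, 60)


def _age_category(ages, breaks) -> pd.Series:
    bins = [-np.inf, *breaks, np.inf]
    labels = [f"<{breaks[0]}"] + [
        f"{lo}-{hi - 1}" for lo, hi in zip(breaks[:-1], breaks[1:])
    ] + [f">={breaks[-1]}"]
    return pd.cut(pd.Series(ages), bins=bins, labels=labels, right=False)


def covariate_table(cohort: pd.DataFrame, gps: pd.DataFrame, breaks) -> pd.DataFrame:
    """Per-patient model covariates for one cohort.

    Patient age is categorised at the cohort's index date; GP age at the
    window start. Condition flags default to False when no timeline was
    attached upstream.
    """
    cov = cohort[["patient_id", "gp_id", "gender"]].rename(
        columns={"gender": "patient_gender"}
    )
    age = ages_at(cohort["birth_year"], cohort["index_date"])
    cov["patient_age_cat"] = _age_category(age, breaks).astype(object)
    for cond in CONDITIONS:
        col = f"has_{cond}"
        cov[col] = cohort[col] if col in cohort else False
    gp = gps.set_index("gp_id")
    cov["gp_gender"] = cohort["gp_id"].map(gp["gender"]).replace("unknown", np.nan)
    gp_age = 2013.0 - gp["birth_year"]
    cov["gp_age_cat"] = _age_category(
        cohort["gp_id"].map(gp_age), GP_AGE_BREAKS
    ).astype(object)
    cov["urban_location"] = cohort["gp_id"].map(gp["urban_location"]).astype(object)
    return cov


def describe_cohort(cohort: pd.DataFrame, dataset: EmrDataset) -> pd.DataFrame:
    """Characteristics table: counts/percentages and median (IQR) rows.

    Percentages use pairwise deletion (denominator = patients with the
    variable observed); the latest lab/vital value per patient at or
    after nothing in particular — simply the latest in the study window —
    feeds the median (IQR) summaries, with the number of patients
    contributing reported alongside.
    """
    rows: list[dict] = []
    n = len(cohort)
    name = cohort["cohort"].iloc[0] if "cohort" in cohort and n else "cohort"
    rows.append({"variable": "n", "level": "", "value": f"{n}"})

    def cat_block(label, series):
        s = series.dropna()
        for level, count in s.value_counts().items():
            rows.append(
                {
                    "variable": label,
                    "level": str(level),
                    "value": f"{count} ({100.0 * count / len(s):.1f}%)",
                }
            )
        missing = n - len(s)
        rows.append({"variable": label, "level": "missing", "value": f"{missing}"})

    cat_block("gender", cohort["gender"])
    breaks = PATIENT_AGE_BREAKS.get(name, (65, 80))
    age = ages_at(cohort["birth_year"], cohort["index_date"])
    rows.append(
        {
            "variable": "age_at_inclusion",
            "level": "median (IQR)",
            "value": _median_iqr(pd.Series(age)),
        }
    )
    cat_block("age_category", _age_category(age, breaks))
    for cond in CONDITIONS:
        col = f"has_{cond}"
        if col in cohort:
            k = int(cohort[col].sum())
            rows.append(
                {
                    "variable": "predisposing_condition",
                    "level": cond,
                    "value": f"{k} ({100.0 * k / n:.1f}%)" if n else "0",
                }
            )
    for stage_col, label in (
        ("g_stage_at_inclusion", "g_stage"),
        ("a_stage_at_inclusion", "a_stage"),
    ):
        if stage_col in cohort:
            cat_block(label, cohort[stage_col])

    members = set(cohort["patient_id"])
    labs = dataset.labs[dataset.labs["patient_id"].isin(members)]
    latest = (
        labs.sort_values("date", kind="stable").groupby(["patient_id", "analyte"]).tail(1)
    )
    for analyte, grp in latest.groupby("analyte"):
        rows.append(
            {
                "variable": f"latest_{analyte}",
                "level": "median (IQR); n (%)",
                "value": f"{_median_iqr(grp['value'])}; "
                f"{len(grp)} ({100.0 * len(grp) / n:.1f}%)" if n else "",
            }
        )
    vit = dataset.vitals[dataset.vitals["patient_id"].isin(members)].copy()
    vit["bmi_value"] = derive_bmi(vit)
    for col, label in (
        ("systolic_bp", "systolic_bp"),
        ("diastolic_bp", "diastolic_bp"),
        ("bmi_value", "bmi"),
    ):
        present = vit.loc[vit[col].notna(), ["patient_id", "date", col]]
        latest_v = present.sort_values("date", kind="stable").groupby("patient_id").tail(1)
        if len(latest_v):
            rows.append(
                {
                    "variable": f"latest_{label}",
                    "level": "median (IQR); n (%)",
                    "value": f"{_median_iqr(latest_v[col])}; "
                    f"{len(latest_v)} ({100.0 * len(latest_v) / n:.1f}%)" if n else "",
                }
            )
    out = pd.DataFrame(rows)
    out.insert(0, "cohort", name)
    return out


def _median_iqr(s: pd.Series) -> str:
    s = pd.to_numeric(s, errors="coerce").dropna()
    if not len(s):
        return "NA"
    q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


@dataclass
class PipelineResult:
    dataset: EmrDataset
    cohorts: dict[str, pd.DataFrame]
    qi_results: list
    qi_summary: pd.DataFrame
    variation: dict[int, object]
    out_dir: Path | None = None


def run_pipeline(
    *,
    table_paths: dict | None = None,
    ingestion_config: IngestionConfig | dict | None = None,
    synth_config: SimulationConfig | dict | None = None,
    seed: int | None = None,
    rules_config=None,
    qi_config: QiConfig | None = None,
    out_dir: str | Path | None = None,
    fit_models: bool = True,
    agh_nodes: int = 1,
) -> PipelineResult:
    """Run the full analysis; exactly one of ``table_paths`` /
    ``synth_config`` (or ``seed`` alone, implying default synthesis) must
    identify the input. Writes the output bundle when ``out_dir`` is set."""
    if (table_paths is not None) == (synth_config is not None or seed is not None):
        raise ValueError("supply exactly one of table_paths or synth_config/seed")

    manifest: dict = {"version": __version__, "seed": seed}
    if table_paths is not None:
        dataset, report = read_emr_tables(table_paths, ingestion_config)
        manifest["ingestion"] = report.to_dict()
    else:
        if synth_config is None:
            synth_config = SimulationConfig()
        elif isinstance(synth_config, dict):
            synth_config = SimulationConfig.model_validate(synth_config)
        dataset, truth = generate_emr(synth_config, seed=seed)
        manifest["synth_config"] = truth.config.model_dump()

    rules = load_rule_set(rules_config)
    qi_config = qi_config or QiConfig()

    evidence = detect_ckd_all(dataset)
    timelines = label_conditions(dataset, rules)
    baseline = build_baseline(dataset)
    rf = build_rf_cohort(baseline, timelines)
    ckd = build_ckd_cohort(baseline, evidence, timelines)
    cohorts = {"rf": rf, "ckd": ckd, "baseline": baseline}

    qi_results, qi_summary = evaluate_all({"rf": rf, "ckd": ckd}, dataset, qi_config)

    variation: dict[int, object] = {}
    if fit_models:
        cov_rf = covariate_table(rf, dataset.gps, PATIENT_AGE_BREAKS["rf_assessment"])
        cov_ckd = covariate_table(ckd, dataset.gps, PATIENT_AGE_BREAKS["ckd_care"])
        for res in qi_results:
            cov = cov_rf if res.category == "assessment" else cov_ckd
            try:
                variation[res.qi_id] = analyse_qi_variation(
                    res, cov, agh_nodes=agh_nodes
                )
            except FitError as exc:
                variation[res.qi_id] = exc
        qi_summary = qi_summary.copy()
        qi_summary["ror"] = [
            round(v.ror, 1) if not isinstance(v := variation[q], Exception) else np.nan
            for q in qi_summary["qi_id"]
        ]
        qi_summary["icc"] = [
            round(v.icc, 2) if not isinstance(v := variation[q], Exception) else np.nan
            for q in qi_summary["qi_id"]
        ]

    result = PipelineResult(
        dataset=dataset,
        cohorts=cohorts,
        qi_results=qi_results,
        qi_summary=qi_summary,
        variation=variation,
    )
    if out_dir is not None:
        result.out_dir = _write_bundle(result, manifest, Path(out_dir))
    return result


def _model_summary(model) -> dict:
    return {
        "beta": {k: round(float(v), 6) for k, v in model.beta.items()},
        "sigma2_b": round(model.sigma2_b, 6),
        "loglik": round(model.loglik, 4),
        "n_obs": model.n_obs,
        "n_clusters": model.n_clusters,
        "converged": model.converged,
    }


def _write_bundle(result: PipelineResult, manifest: dict, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    chars = pd.concat(
        [
            describe_cohort(result.cohorts["rf"], result.dataset),
            describe_cohort(result.cohorts["ckd"], result.dataset),
        ],
        ignore_index=True,
    )
    write_table(chars, out_dir / "cohort_characteristics.csv")
    summary = result.qi_summary.copy()
    summary["achievement_rate"] = summary["achievement_rate"].round(1)
    write_table(summary, out_dir / "qi_summary.csv")
    for res in result.qi_results:
        write_table(res.per_patient, out_dir / f"per_patient_qi{res.qi_id}.csv")
    for qi_id, v in result.variation.items():
        if isinstance(v, Exception):
            continue
        forest = v.or_table.copy()
        for c in ("or", "ci_low", "ci_high"):
            forest[c] = forest[c].round(2)
        write_table(forest, out_dir / f"forest_qi{qi_id}.csv")
        (out_dir / f"model_qi{qi_id}.json").write_text(
            json.dumps(
                {
                    "qi_id": qi_id,
                    "achievement_rate": round(v.achievement_rate, 1),
                    "ror": round(v.ror, 1),
                    "icc": round(v.icc, 2),
                    "full": _model_summary(v.full_model),
                    "null": _model_summary(v.null_model),
                },
                indent=2,
            )
        )
    manifest["row_counts"] = result.dataset.counts()
    manifest["cohort_sizes"] = {
        "baseline": len(result.cohorts["baseline"]),
        "rf_assessment": len(result.cohorts["rf"]),
        "ckd_care": len(result.cohorts["ckd"]),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir
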