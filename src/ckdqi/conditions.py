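"""Condition labelling: diabetes, hypertension, established CVD.

A configurable rule engine assigns each patient the date of first evidence
of each predisposing condition, scanning ICPC-2 encounter codes, ATC
prescription codes, laboratory values, and vital-sign thresholds. Code
matching is prefix-based because both ICPC-2 and ATC are hierarchical
(``C09`` matches ``C09AA02``). Labels, once acquired, persist — these are
chronic conditions.

The shipped default rule set is a documented approximation of common
primary-care operationalisations; study-specific code lists can replace it
wholesale through a YAML/JSON config.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import EmrDataset

CONDITIONS = ("diabetes", "hypertension", "ecvd")

_COMPARATORS = {
    ">=": operator.ge,
    ">": operator.gt,
    "<=": operator.le,
    "<": operator.lt,
}


@dataclass(frozen=True)
class LabCriterion:
    analyte: str
    comparator: str
    threshold: float


@dataclass(frozen=True)
class VitalCriterion:
    field: str
    comparator: str
    threshold: float
    min_occurrences: int = 1


@dataclass
class ConditionRule:
    icpc2_codes: tuple[str, ...] = ()
    atc_codes: tuple[str, ...] = ()
    lab_criteria: tuple[LabCriterion, ...] = ()
    vital_criteria: tuple[VitalCriterion, ...] = ()


@dataclass
class ConditionRuleSet:
    rules: dict[str, ConditionRule] = field(default_factory=dict)

    def __getitem__(self, condition: str) -> ConditionRule:
        return self.rules[condition]


def _default_config() -> dict:
    with resources.files("ckdqi.config").joinpath("default_conditions.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_rule_set(config: dict | str | Path | None = None) -> ConditionRuleSet:
    """Build a rule set from a config mapping or YAML path; None -> defaults.

    A config overrides conditions key-by-key; unknown condition keys and
    non-positive thresholds are hard errors.
    """
    merged = _default_config()
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                config = yaml.safe_load(fh) or {}
        unknown = set(config) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition key(s): {sorted(unknown)}")
        for cond, override in config.items():
            merged[cond] = {**merged[cond], **(override or {})}

    rules: dict[str, ConditionRule] = {}
    for cond in CONDITIONS:
        spec = merged[cond]
        labs = tuple(LabCriterion(**c) for c in spec.get("lab_criteria", []))
        vitals = tuple(VitalCriterion(**c) for c in spec.get("vital_criteria", []))
        for crit in (*labs, *vitals):
            if crit.comparator not in _COMPARATORS:
                raise ValueError(f"unknown comparator {crit.comparator!r}")
            if crit.threshold <= 0:
                raise ValueError(f"non-positive threshold in {cond} criterion: {crit}")
        for v in vitals:
            if v.min_occurrences < 1:
                raise ValueError("min_occurrences must be >= 1")
        rules[cond] = ConditionRule(
            icpc2_codes=tuple(spec.get("icpc2_codes", []) or []),
            atc_codes=tuple(spec.get("atc_codes", []) or []),
            lab_criteria=labs,
            vital_criteria=vitals,
        )
    return ConditionRuleSet(rules=rules)


def _prefix_match(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=codes.index)
    return codes.str.startswith(tuple(prefixes), na=False)


def _criterion_dates(dataset: EmrDataset, rule: ConditionRule):
    """Yield (patient_id -> first firing date) Series, one per criterion."""
    enc = dataset.encounters
    if rule.icpc2_codes and len(enc):
        hit = enc.loc[_prefix_match(enc["icpc2_code"], rule.icpc2_codes)]
        yield hit.groupby("patient_id")["date"].min()
    rx = dataset.prescriptions
    if rule.atc_codes and len(rx):
        hit = rx.loc[_prefix_match(rx["atc_code"], rule.atc_codes)]
        yield hit.groupby("patient_id")["date"].min()
    labs = dataset.labs
    for crit in rule.lab_criteria:
        if not len(labs):
            continue
        rows = labs.loc[labs["analyte"] == crit.analyte]
        fires = _COMPARATORS[crit.comparator](rows["value"], crit.threshold)
        yield rows.loc[fires].groupby("patient_id")["date"].min()
    vit = dataset.vitals
    for crit in rule.vital_criteria:
        if not len(vit) or crit.field not in vit.columns:
            continue
        vals = pd.to_numeric(vit[crit.field], errors="coerce")
        fires = _COMPARATORS[crit.comparator](vals, crit.threshold)
        hit = vit.loc[fires.fillna(False)]
        # date the occurrence count is reached: k-th earliest qualifying date
        k = crit.min_occurrences
        ordered = hit.sort_values("date", kind="stable")
        nth_mask = ordered.groupby("patient_id").cumcount() == k - 1
        yield ordered.loc[nth_mask].set_index("patient_id")["date"]


def label_conditions(
    dataset: EmrDataset, rules: ConditionRuleSet | None = None
) -> pd.DataFrame:
    """First-evidence date per condition per patient.

    Returns a DataFrame indexed 0..n-1 with columns ``patient_id`` and
    ``first_<condition>`` (NaT where the condition never fires). The first
    evidence date is the earliest date at which any single criterion of the
    condition's rule fires.
    """
    if rules is None:
        rules = load_rule_set()
    out = dataset.patients[["patient_id"]].copy()
    for cond in CONDITIONS:
        firsts = [s for s in _criterion_dates(dataset, rules[cond])]
        if firsts:
            combined = pd.concat(firsts).groupby(level=0).min()
        else:
            combined = pd.Series(dtype="datetime64[ns]")
        out[f"first_{cond}"] = pd.to_datetime(out["patient_id"].map(combined))
    return out
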