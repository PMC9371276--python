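# ckdqi

Quality-of-care indicators and physician-level variation analysis for
chronic kidney disease (CKD) in longitudinal primary-care EMR data.

Routine general-practice records — encounters coded in ICPC-2,
prescriptions in ATC, laboratory results, and vital signs — contain
enough signal to measure how well CKD is detected, monitored, and
treated, and how much of that quality varies between individual
physicians rather than between patients. `ckdqi` packages that analysis
for health-services researchers: it ingests six delimited EMR tables,
detects laboratory-confirmed CKD, builds the study cohorts, evaluates 14
quality indicators (QIs), and quantifies GP-level variation with
random-intercept logistic models. A synthetic EMR generator with exported
ground truth makes every stage testable without access to patient data.

## The models at the core

**Case detection.** eGFR is estimated from serum creatinine with the 2009
CKD-EPI equation (no ethnicity term),

> eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female],

and staged into KDIGO G1–G5 / A1–A3 categories. A patient has
laboratory-confirmed CKD upon two eGFR values <60 mL/min/1.73 m², and/or
two urinary albumin concentrations ≥20 mg/L, and/or two
albumin-to-creatinine ratios ≥3 mg/mmol, at least 90 days apart.

**Quality indicators.** Each QI is a numerator/denominator rule over a
cohort: renal-function assessment within 18 months of a predisposing
condition (diabetes, hypertension, established CVD); stage-appropriate
monitoring within 18 months of CKD confirmation; RAAS-inhibitor/statin
prescribing and NSAID withholding within 12 months; and latest-value
blood-pressure and BMI targets. The achievement rate is
100·|numerator|/|denominator|.

**Variation.** For each QI, achievement is modelled as
logit P(y_ig=1) = x_ig′β + b_g with GP intercepts b_g ~ N(0, σ_b²),
fitted by maximum likelihood (Laplace approximation, optional adaptive
Gauss–Hermite). Fixed effects are reported as odds ratios with Wald 95%
CIs; GP-level variation as the latent-scale intraclass correlation
ICC = σ_b²/(σ_b² + π²/3) and the range odds ratio
rOR = exp(q95 − q05) over the central 90% of predicted intercepts, both
from the null model that omits GP-level fixed effects.

## Worked example

```python
from ckdqi import run_pipeline

result = run_pipeline(seed=42, fit_models=False)
print(result.qi_summary.round(1).to_string(index=False))
```

On the default synthetic registry (60 GPs, ~4,800 patients) this prints:

```
        category  qi_id                             description  n_denominator  achievement_rate
      assessment      1                       RF; diabetes (18)            865              81.7
      assessment      2                   RF; hypertension (18)           3229              78.0
      assessment      3                           RF; eCVD (18)            407              81.8
      monitoring      4                     eGFR/SCr; G1-4 (18)            750              82.1
      monitoring      5                      ACR/UAC; G1-4 (18)            750              24.5
      monitoring      6                        RF+BP; G2-4 (18)            733              85.5
      monitoring      7              RF+BP+CBC+chem; G3a-4 (18)            690              63.6
      monitoring      8          RF+BP+CBC+chem+MBD; G3b-4 (18)            184              38.6
      medication      9               RAAS inhibitor; G1-4 (12)            894              59.1
      medication     10          Statin; G1-4, 50-80 years (12)            526              46.0
      medication     11              Withheld NSAID; G2-3b (12)            842              85.7
treatment_target     12           Latest BP < 140/90 mmHg; G1-4           1128              61.1
treatment_target     13 Latest BP < 130/80 mmHg; G1-4, diabetes            350              24.6
treatment_target     14            Latest BMI 20-25 kg/m2; G1-4            985              24.6
```

Each row is one indicator: `n_denominator` patients met the clinical
eligibility rule, and `achievement_rate` is the percentage for whom the
indicated care event occurred (or, for NSAIDs, was withheld). With
`fit_models=True` (the default) the summary gains `ror` and `icc`
columns from the per-QI null models, and `result.variation[qi_id]`
carries the full odds-ratio tables. Estimating variation directly:

```python
from ckdqi import (fit_random_intercept_logistic, generate_clustered_binary,
                   icc_latent, range_or)

df, truth = generate_clustered_binary(300, 80, sigma_b=1.0, beta={"male": 0.4}, seed=3)
model = fit_random_intercept_logistic(df, "y", ("male",), "gp_id")
print(round(model.sigma_b, 3), round(icc_latent(model.sigma2_b), 3),
      round(range_or(model.intercepts), 1))
# 1.001 0.233 26.2   (truth: 1.0, 0.233, 26.8 in the large-sample limit)
```

The `examples/` directory walks through each capability; the `ckdqi`
command (`ckdqi run`, `ckdqi synth`, `ckdqi validate`) exposes the
pipeline from the shell, writing CSV/JSON bundles with a run manifest.

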