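# Methods

This note documents the models and procedures implemented in `ckdqi`, the
assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Renal function and CKD case detection

eGFR is computed with the 2009 CKD-EPI creatinine equation. With serum
creatinine Scr in mg/dL (stored internally in µmol/L; 1 mg/dL =
88.42 µmol/L), κ = 0.7 / 0.9 and α = −0.329 / −0.411 for female / male
patients:

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female]

No ethnicity coefficient is applied; the data model carries no ethnicity
field. The equation is undefined for patients of other gender, whose
creatinine values therefore yield a missing derived eGFR (a reported eGFR
value remains usable). A reported eGFR always takes precedence over a
same-day creatinine-derived one.

KDIGO stages: G1 ≥90, G2 60–89, G3a 45–59, G3b 30–44, G4 15–29, G5 <15
mL/min/1.73 m² (lower edges inclusive); A1 <3, A2 3–30, A3 >30 mg/mmol
ACR (30 itself is A2).

A patient has laboratory-confirmed CKD upon two eGFR values <60, and/or
two UAC values ≥20 mg/L, and/or two ACR values ≥3 mg/mmol, at least
three months apart, each criterion evaluated on its own analyte series.
Numerical choices:

* "3 months apart" means a date difference ≥90 days
  (`DetectionThresholds.min_gap_days`, configurable). Day arithmetic
  avoids calendar-month ambiguity.
* The two qualifying values need not be consecutive; intervening normal
  values never reset or un-confirm. Adding measurements can only keep or
  advance the confirmation date (a tested invariant).
* The evidence date is the second (confirming) measurement's date — CKD
  cannot be asserted before two values exist. All follow-up windows
  anchor there.
* Stage at inclusion is the stage of the most recent measurement of the
  staging analyte (eGFR for G, ACR for A) at or before the evidence date;
  patients confirmed by albuminuria alone can therefore carry G1/G2
  stages, and the A stage is missing when no ACR exists (UAC has no
  A-binning).
* `ever_g5` is true if any eGFR <15 occurs anywhere in the series.

## Condition labelling

Diabetes, hypertension, and established cardiovascular disease are
labelled by a config-first rule engine over ICPC-2 codes, ATC codes,
laboratory values, and vital-sign thresholds. Matching is prefix-based
because both code systems are hierarchical. The first-evidence date is
the earliest date any single criterion fires; for k-occurrence vital
criteria it is the date the k-th qualifying reading accrues. Labels
persist once acquired (chronic conditions). The shipped default lists
(`ckdqi/config/default_conditions.yaml`) are documented approximations of
common primary-care operationalisations — site-specific lists should be
supplied via config for exact replication of any particular registry
study. The hypertension blood-pressure rule is expressed as two
single-field criteria (two systolic readings ≥140, or two diastolic
readings ≥90), the closest encoding of "two readings ≥140/90" available
in the single-field criterion schema.

## Cohorts and windows

* Baseline: ≥1 encounter in the study window (default 2013-01-01 to
  2019-12-31) and age ≥18 at the first observed event of any type.
* RF assessment cohort: baseline patients with ≥18 months between a
  predisposing condition's first evidence and the last recorded contact,
  tracked per condition so each assessment indicator uses its own index.
* CKD care cohort: baseline patients with confirmed CKD, excluding anyone
  ever staged G5; index = evidence date.

Follow-up ends at the last recorded contact of any event type — the data
carry no explicit censoring date, so observed activity is the
conservative, data-driven bound. Window constants are fixed day counts:
18 months = 548 days, 12 months = 365 days; follow-up in months divides
days by 30.4375. Windows are half-open `[index, index+W)`.

## Quality indicators

Event semantics are shared across the 14 indicators: a renal-function
assessment is any serum-creatinine/eGFR or albuminuria measurement (the
broad reading is used for the "RF" component of the stage-monitoring
indicators as well); CBC = haemoglobin; chemistry = urea, sodium or
potassium; mineral-and-bone = alkaline phosphatase, calcium, phosphate or
parathyroid hormone; RAAS inhibitors are ATC `C09*`; statins `C10AA*` and
combinations `C10B*`; NSAIDs `M01A*` with aspirin-containing codes
(`B01AC06`, `N02BA01`, `M01BA*`) never counted.

Decisions worth knowing:

* Monitoring indicators (4–8) count events strictly after the index date:
  the lab that confirms CKD does not double as its own follow-up.
  Assessment (1–3) and medication (9–11) windows include the index day.
  The switch is `QiConfig.monitoring_excludes_index_date`.
* "Active prescription within 12 months" means a start date inside the
  window, or a `[start, end]` interval overlapping it when an end date is
  recorded (end dates are optional in the data model).
* Blood-pressure targets require both components of the latest *complete*
  reading after the index date (<140/90; <130/80 for the diabetic
  indicator, whose denominator is patients with diabetes evidence
  anywhere in the window). Incomplete readings are skipped when choosing
  the latest.
* BMI uses the recorded value where present, else weight/height², and the
  20–25 kg/m² target is a closed interval. The statin indicator's 50–80
  year age band is evaluated at the index date, bounds inclusive.
* Stage-restricted denominators require a non-missing G stage at
  inclusion in the listed range; albuminuria-confirmed patients without
  any eGFR measurement have no G stage and are not members.

## GP-level variation

For each indicator, achievement is modelled as

    logit P(y_ig = 1) = x_ig'β + b_g,   b_g ~ N(0, σ_b²),

with one random intercept per GP. The marginal likelihood is maximised
over (β, log σ_b) by L-BFGS-B; each cluster's 1-D integral is
approximated by the Laplace method at the per-cluster posterior mode
(vectorised Newton ascent), optionally refined by adaptive Gauss–Hermite
quadrature (`agh_nodes`). The objective is deterministic; starting values
come from a plain logistic fit with σ_b = 0.5; convergence tolerance is
1e-8 on the log-likelihood, with log σ_b bounded in [−7, 3]. Standard
errors come from the inverted finite-difference Hessian at the optimum;
odds-ratio CIs are Wald intervals (exp(β ± 1.959964·SE)) — cheap and
conventional, not profile-likelihood. Predicted intercepts are the
posterior modes at the ML estimates; their empirical variance is smaller
than σ̂_b² (shrinkage), which biases the range odds ratio slightly toward
1 at small cluster sizes.

Variation summaries, both read off the *null* model (GP-level fixed
effects omitted, so GP influence loads entirely on the intercept):

* ICC = σ_b² / (σ_b² + π²/3), the latent-threshold variance partition for
  logistic models. This scale is fixed; alternatives (e.g. observed-scale
  ICCs) are deliberately not offered.
* rOR = exp(q95 − q05) over the predicted intercepts, with percentiles by
  linear interpolation between order statistics (the numpy default). The
  estimator choice matters at small cluster counts, which is why it is
  pinned here. rOR ≥ 1 by construction. For normal intercepts the
  large-sample value is exp(3.2897·σ_b).

Model rows: patients of "other" gender are excluded (they are retained in
descriptive output); remaining missingness is handled by listwise
deletion, descriptives by pairwise deletion. Full models include patient
gender, patient age category (cohort-specific bands: <40/40–59/60–79/≥80
for the RF cohort, <65/65–79/≥80 for the CKD cohort), condition flags,
GP gender, GP age category (<45/45–60/≥60), and practice urbanity.

## Synthetic data generator

`generate_emr` emulates the structure the analysis assumes: patients
clustered within GPs (negative-binomial panel sizes), independent per-GP
normal intercepts for each care behaviour (renal-function testing,
albuminuria testing, RAAS/statin/NSAID prescribing, blood-pressure
control), a homogeneous-Poisson visit process (default 4 visits/year),
linearly declining true eGFR with multiplicative lab noise, logistic
condition prevalences in age, condition-defining ICPC-2/ATC events, and
BP/BMI measurements. All draws flow from one `numpy` generator seeded
from the config, giving bit-reproducible datasets.

Default parameters were chosen once to resemble an elderly primary-care
registry: intercept SDs of 1.1 for testing behaviours and 0.45–0.5 for
prescribing/BP control (implying ICCs near 0.27 and 0.06–0.07, the two
regimes seen in such data), per-visit testing propensities that yield
~75–80% renal-function assessment and ~20–30% albuminuria assessment over
18 months, and an age distribution (mean 62, SD 16) under which roughly a
quarter of patients acquire laboratory CKD. Known deviations from real
registries: the stage mix at inclusion concentrates more in G3a (~68%)
than published cohorts, the diabetic blood-pressure target is achieved
less often, and the generator models no referral, death, or drop-out —
censoring is visit-process-driven only. One intercept per behaviour is
drawn independently; correlated "GP quality" across behaviours is a
config extension, not a default. Passing recovery tests on this generator
therefore demonstrates correctness of the estimation machinery under the
assumed model, not robustness to real-EMR artefacts such as informative
visiting, coding drift, or unit errors beyond those the ingester handles.

`generate_clustered_binary` bypasses the EMR plumbing entirely and is the
harness for estimator-recovery tests.

## Problem sizes and tolerances in the shipped checks

The default test-and-acceptance configuration fits the study on a 60-GP,
~4,800-patient synthetic registry (the full pipeline, all 14 indicators,
28 model fits, ~15 s) and verifies estimator recovery on 200-cluster ×
100-observation designs (50 replicates; mean σ̂_b within ±0.15 of 1.0,
mean intercept within ±0.1 of −0.5) and the analytic rOR/ICC limits at
500 clusters (±20% / ±0.03). The marginal likelihood is checked against
independent scipy quadrature at 1e-4 in the fitter's Gauss–Hermite mode;
the pure Laplace value carries an O(1/n_cluster) approximation error and
is instead checked for error decay with cluster size. Cross-validation
against `lme4::glmer` runs on a 60×40 design with agreement to ±0.05 on
coefficients and 10% on the variance component.

## Known limitations

* Exact replication of any specific registry study requires that study's
  operational code lists and unit conventions via config; the shipped
  defaults are approximations.
* The fitter supports one random intercept (no random slopes, no second
  clustering level such as practice-within-region); profile-likelihood
  CIs and small-sample corrections for σ_b are not implemented.
* Year-resolution ages (birth years only) make ages accurate to ±1 year
  around birthdays; all window arithmetic is day-resolution.
* The rOR is reported from empirical percentiles of shrunken predicted
  intercepts; with few clusters it under-states the latent range.
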