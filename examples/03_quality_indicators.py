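"""Run the full quality-indicator pipeline on synthetic data.

Synthesises an EMR, detects CKD, labels predisposing conditions, builds
the two study cohorts, and evaluates all 14 quality indicators. Rates are
percentages of each indicator's denominator population.
"""

from ckdqi import run_pipeline

result = run_pipeline(seed=42, fit_models=False)

rf, ckd = result.cohorts["rf"], result.cohorts["ckd"]
print(f"baseline {len(result.cohorts['baseline'])} patients; "
      f"RF assessment cohort {len(rf)}; CKD care cohort {len(ckd)}")
staged = ckd["g_stage_at_inclusion"].dropna()
print(f"G3a share at inclusion: {100 * (staged == 'G3a').mean():.1f}%")
print()
print(result.qi_summary.round(1).to_string(index=False))
# Assessment/monitoring indicators use an 18-month window after the index
# date, medication indicators 12 months, and treatment targets the latest
# measurement after CKD confirmation.
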