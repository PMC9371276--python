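"""Estimate eGFR, stage renal function, and detect laboratory CKD.

Builds a short creatinine/albuminuria history for one fictional patient
and runs it through the CKD-EPI equation, KDIGO staging, and the
two-abnormal-values case-detection rule.
"""

import pandas as pd

from ckdqi import ckd_epi_egfr, detect_ckd, stage_a, stage_g

# A 70-year-old man with serum creatinine 150 umol/L
egfr = ckd_epi_egfr(150.0, age=70, sex="male")
print(f"eGFR for SCr 150 umol/L, male, 70y: {egfr:.1f} mL/min/1.73m2")
print(f"KDIGO G stage: {stage_g(egfr)}   (A stage for ACR 4.2: {stage_a(4.2)})")

# Longitudinal series: two eGFR values < 60 more than 90 days apart confirm CKD
series = pd.DataFrame(
    [
        {"date": "2014-01-10", "egfr": 55.0, "acr": None, "uac": None},
        {"date": "2014-02-20", "egfr": 72.0, "acr": None, "uac": None},  # transient recovery
        {"date": "2014-09-15", "egfr": 52.0, "acr": 4.2, "uac": None},
    ]
)
evidence = detect_ckd(series, patient_id="example")
print(
    f"CKD confirmed: {evidence.ckd_confirmed} on {evidence.evidence_date.date()} "
    f"via {evidence.criterion}; stage at inclusion {evidence.g_stage_at_inclusion}"
)
# The confirmation date is the second qualifying measurement; the normal
# value in between does not reset the rule.
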