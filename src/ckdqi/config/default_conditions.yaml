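# Default operationalisation of the three predisposing conditions.
# Code lists are documented approximations of common primary-care usage;
# site-specific lists can be dropped in verbatim via this config.
diabetes:
  icpc2_codes: [T89, T90]
  atc_codes: [A10]
  lab_criteria:
    - {analyte: hba1c, comparator: ">=", threshold: 6.5}
  vital_criteria: []
hypertension:
  icpc2_codes: [K86, K87]
  atc_codes: [C02, C03, C07, C08, C09]
  lab_criteria: []
  vital_criteria:
    - {field: systolic_bp, comparator: ">=", threshold: 140, min_occurrences: 2}
    - {field: diastolic_bp, comparator: ">=", threshold: 90, min_occurrences: 2}
ecvd:
  icpc2_codes: [K74, K75, K76, K89, K90, K91, K92]
  atc_codes: []
  lab_criteria: []
  vital_criteria: []
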