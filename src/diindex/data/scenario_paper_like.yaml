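n_participants: 20000
seed: 7
reference: null
spread_scale: 1.0
demographics:
  age_mean: 59.0
  age_sd: 15.0
  age_range:
  - 20.0
  - 85.0
  p_male: 0.48
  bmi_mean: 31.0
  bmi_sd: 7.0
  bmi_range:
  - 15.0
  - 70.0
  race:
    Mexican American: 0.14
    Other Hispanic: 0.079
    Non-Hispanic white: 0.453
    Non-Hispanic black: 0.248
    Other race or multi-racial: 0.08
  education:
    <High school: 0.281
    High school: 0.24
    '>High school': 0.479
  income_band:
    <20,000 USD: 0.283
    '>=20,000 USD': 0.717
  smoking:
    Smoking: 0.374
    Non-smoking: 0.626
condition_prevalences:
  hypertension: 0.35
  diabetes: 0.12
  prediabetes: 0.1
  coronary_artery_disease: 0.04
  angina: 0.025
  heart_attack: 0.04
  stroke: 0.04
latent_loading: 0.8
qualifying_fraction: 0.6
hf_model:
  or_dii: 1.15
  or_age: 1.05
  or_female: 0.61
  or_bmi: 1.05
  intercept: -6.95
missingness:
  heart_failure: 0.02
  diet: 0.05
  bmi: 0.03
  waist_cm: 0.03
  education: 0.002
  income_band: 0.04
  smoking: 0.5
  labs: 0.1
lab_model:
  lab_total_cholesterol:
    mean: 5.05
    sd: 1.14
    hf_shift: -0.44
  lab_hdl:
    mean: 1.36
    sd: 0.42
    hf_shift: -0.1
  lab_ldl:
    mean: 2.91
    sd: 0.93
    hf_shift: -0.33
  lab_triglyceride:
    mean: 1.62
    sd: 1.34
    hf_shift: 0.15
  lab_albumin:
    mean: 41.63
    sd: 3.42
    hf_shift: -1.36
  lab_globulin:
    mean: 30.0
    sd: 5.5
    hf_shift: 1.3
  lab_hemoglobin:
    mean: 13.98
    sd: 1.55
    hf_shift: -0.43
  lab_hematocrit:
    mean: 41.35
    sd: 4.38
    hf_shift: -1.06
  lab_bun:
    mean: 5.41
    sd: 2.45
    hf_shift: 2.02
  lab_creatinine:
    mean: 0.97
    sd: 0.58
    hf_shift: 0.33
  lab_uric_acid:
    mean: 339.32
    sd: 88.29
    hf_shift: 46.9
  lab_wbc:
    mean: 7.38
    sd: 2.5
    hf_shift: 0.22
  lab_pulse_rate:
    mean: 72.59
    sd: 12.79
    hf_shift: -1.75
  lab_systolic_bp:
    mean: 130.0
    sd: 20.0
    hf_shift: 2.0
  lab_diastolic_bp:
    mean: 71.1
    sd: 14.97
    hf_shift: -4.62
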