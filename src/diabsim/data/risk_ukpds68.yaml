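# Base-case macrovascular / first-ever-event risk equations, Weibull
# proportional-hazards form with diabetes duration as the time scale:
#   L = intercept + sum_j coef_j * (covariate_j - center_j)
#   P(event in year) = 1 - exp(exp(L) * (t^shape - (t+1)^shape)),  t = duration
# Covariate sets and centering follow the published diabetes outcomes
# equations (age at diagnosis, sex, smoking, HbA1c, SBP, lipid ratio, BMI);
# the published coefficient values themselves are not reproduced here, so
# these files ship plausible transcription-style defaults and are the
# user-editable control surface for the risk engine.
equations:
- outcome: mi_event
  form: weibull_ph
  shape: 1.30
  intercept: -6.10
  coefficients: {age_diag: 0.055, female: -0.83, smoker: 0.35, hba1c: 0.12, sbp10: 0.10, lipid_ratio: 0.10}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, lipid_ratio: 5.2, hba1c: 6.72}
  source_label: ukpds68-style default
- outcome: stroke_event
  form: weibull_ph
  shape: 1.50
  intercept: -7.60
  coefficients: {age_diag: 0.085, female: -0.52, smoker: 0.35, hba1c: 0.09, sbp10: 0.28}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, hba1c: 6.72}
  source_label: ukpds68-style default
- outcome: chf_event
  form: weibull_ph
  shape: 1.70
  intercept: -8.10
  coefficients: {age_diag: 0.093, bmi: 0.05, hba1c: 0.15, egfr: -0.005}
  covariate_centering: {age_diag: 50.0, bmi: 27.8, hba1c: 6.72, egfr: 90.0}
  source_label: ukpds68-style default
- outcome: angina_event
  form: weibull_ph
  shape: 1.20
  intercept: -6.30
  coefficients: {age_diag: 0.060, female: -0.56, hba1c: 0.13}
  covariate_centering: {age_diag: 50.0, hba1c: 6.72}
  source_label: ukpds68-style default
- outcome: pvd_event
  form: weibull_ph
  shape: 1.40
  intercept: -7.40
  coefficients: {age_diag: 0.050, smoker: 0.96, hba1c: 0.25, sbp10: 0.08}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, hba1c: 6.72}
  source_label: ukpds68-style default
- outcome: renal_failure_event
  form: weibull_ph
  shape: 1.80
  intercept: -9.60
  coefficients: {sbp10: 0.40, hba1c: 0.20, female: 0.29, egfr: -0.02}
  covariate_centering: {sbp10: 13.5, hba1c: 6.72, egfr: 90.0}
  source_label: ukpds68-style default
- outcome: amputation_event
  form: weibull_ph
  shape: 1.60
  intercept: -9.10
  coefficients: {age_diag: 0.04, hba1c: 0.40, sbp10: 0.09, active_ulcer: 2.0, neuropathy_flag: 0.8}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, hba1c: 6.72}
  source_label: ukpds68-style default
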