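# Alternative risk-equation set (sensitivity analysis), same functional
# forms as the base-case file but with the later equation set's broader
# covariate usage (eGFR in more equations, attenuated HbA1c slopes).
# Values are user-editable defaults, not published coefficients.
equations:
- outcome: mi_event
  form: weibull_ph
  shape: 1.25
  intercept: -6.30
  coefficients: {age_diag: 0.050, female: -0.75, smoker: 0.30, hba1c: 0.10, sbp10: 0.09, lipid_ratio: 0.08, egfr: -0.004}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, lipid_ratio: 5.2, hba1c: 6.72, egfr: 90.0}
  source_label: ukpds82-style default
- outcome: stroke_event
  form: weibull_ph
  shape: 1.45
  intercept: -7.80
  coefficients: {age_diag: 0.080, female: -0.48, smoker: 0.30, hba1c: 0.08, sbp10: 0.25, egfr: -0.004}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, hba1c: 6.72, egfr: 90.0}
  source_label: ukpds82-style default
- outcome: chf_event
  form: weibull_ph
  shape: 1.65
  intercept: -8.30
  coefficients: {age_diag: 0.090, bmi: 0.06, hba1c: 0.12, egfr: -0.006}
  covariate_centering: {age_diag: 50.0, bmi: 27.8, hba1c: 6.72, egfr: 90.0}
  source_label: ukpds82-style default
- outcome: angina_event
  form: weibull_ph
  shape: 1.20
  intercept: -6.50
  coefficients: {age_diag: 0.055, female: -0.50, hba1c: 0.11}
  covariate_centering: {age_diag: 50.0, hba1c: 6.72}
  source_label: ukpds82-style default
- outcome: pvd_event
  form: weibull_ph
  shape: 1.35
  intercept: -7.60
  coefficients: {age_diag: 0.045, smoker: 0.90, hba1c: 0.22, sbp10: 0.07}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, hba1c: 6.72}
  source_label: ukpds82-style default
- outcome: renal_failure_event
  form: weibull_ph
  shape: 1.75
  intercept: -9.80
  coefficients: {sbp10: 0.35, hba1c: 0.18, female: 0.25, egfr: -0.03}
  covariate_centering: {sbp10: 13.5, hba1c: 6.72, egfr: 90.0}
  source_label: ukpds82-style default
- outcome: amputation_event
  form: weibull_ph
  shape: 1.55
  intercept: -9.30
  coefficients: {age_diag: 0.035, hba1c: 0.35, sbp10: 0.08, active_ulcer: 2.0, neuropathy_flag: 0.8}
  covariate_centering: {age_diag: 50.0, sbp10: 13.5, hba1c: 6.72}
  source_label: ukpds82-style default
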