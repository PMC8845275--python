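# Base-case simulation configuration: lifetime (50-year) horizon, 4% annual
# discounting of both costs and effects, per-patient treatment
# intensification once end-of-cycle HbA1c strictly exceeds 7.5%, and
# post-intensification hypoglycemia rates of 4.08 (non-severe) and 0.10
# (severe) events per patient-year on basal insulin.
# The HbA1c autoregression defaults are calibrated so that, from the
# packaged baselines and first-year effects, the cohort mean time on initial
# therapy rounds to 3 years (oral semaglutide, dulaglutide) and 2 years
# (empagliflozin).
horizon_years: 50
discount_rate_costs: 0.04
discount_rate_effects: 0.04
n_patients: 10000
seed: 12345
switch_threshold_hba1c: 7.5
switch_fixed_year: null
intensification_policy:
  kind: willis_linear
  willis_intercept: -2.55
  willis_slope: 0.45
  target_hba1c: 7.0
hba1c_law:
  kind: ukpds_ar
  ar_weight: 0.72
  attractor_intercept: 7.8
  attractor_slope: 0.05
  linear_slope: 0.15
secondary_drift:
  sbp: {ar_weight: 0.97, attractor: 145.0}
  tc: {ar_weight: 0.98, attractor: 195.0}
  hdl: {ar_weight: 1.0, attractor: 45.0}
bmi_persistence: revert_on_switch
risk_set: ukpds68
basal_nonsevere_hypo_rate: 4.08
basal_severe_hypo_rate: 0.10
utility_model_bmi: beaudet
hypo_disutility_model: evans
death_accrual: half_cycle
complication_cost_multiplier: 1.0
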