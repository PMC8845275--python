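# Baseline cohort characteristics of the two trial populations.
# Continuous characteristics are mean (sd).  Lipid and eGFR baselines were
# not published for these cohorts; the values below are documented defaults
# (overridable) chosen to keep the macrovascular risk equations runnable.
pioneer2:
  label: "PIONEER 2 (oral semaglutide vs empagliflozin)"
  start_age: {mean: 57.63, sd: 9.94}
  diabetes_duration: {mean: 7.00, sd: 6.09}
  proportion_male: 0.5055
  hba1c: {mean: 8.14, sd: 0.94}
  sbp: {mean: 132.15, sd: 14.69}
  bmi: {mean: 32.82, sd: 6.11}
  total_cholesterol: {mean: 180.0, sd: 40.0}   # default, not published
  hdl: {mean: 45.0, sd: 12.0}                  # default, not published
  egfr: {mean: 90.0, sd: 20.0}                 # default, not published
  proportion_smoker: 0.1462
  cigarettes_per_day: 13
  alcohol_oz_per_week: 7.97
pioneer3:
  label: "PIONEER 3 (oral semaglutide vs dulaglutide, NMA comparison)"
  start_age: {mean: 57.86, sd: 9.87}
  diabetes_duration: {mean: 9.00, sd: 5.98}
  proportion_male: 0.5282
  hba1c: {mean: 8.31, sd: 0.92}
  sbp: {mean: 133.83, sd: 15.41}
  bmi: {mean: 32.49, sd: 6.41}
  total_cholesterol: {mean: 180.0, sd: 40.0}   # default, not published
  hdl: {mean: 45.0, sd: 12.0}                  # default, not published
  egfr: {mean: 90.0, sd: 20.0}                 # default, not published
  proportion_smoker: 0.1417
  cigarettes_per_day: 13
  alcohol_oz_per_week: 7.97
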