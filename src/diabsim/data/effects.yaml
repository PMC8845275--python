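# First-year treatment effects (mean change from baseline, standard error)
# and adverse-event rates applied while patients receive initial therapies.
# Hypoglycemia rates are events per 100 patient-years.  `significant` marks a
# statistically significant difference vs the comparator at the 95% level.
# eGFR changes were not reported and are set to zero in all arms; serum
# lipid changes and hypoglycemia were not included in the network
# meta-analysis and are therefore zero in the `nma` block.
pioneer2:
  intervention:
    arm_name: oral_semaglutide
    delta_hba1c: {mean: -1.30, se: 0.05, significant: true}
    delta_sbp: {mean: -4.85, se: 0.65, significant: false}
    delta_tc: {mean: -5.08, se: 1.62, significant: true}
    delta_hdl: {mean: 0.73, se: 0.35, significant: true}
    delta_bmi: {mean: -1.73, se: 0.10, significant: true}
    delta_egfr: {mean: 0.0, se: 0.0, significant: false}
    nonsevere_hypo_rate: 2.25
    severe_hypo_rate: 0.25
    nocturnal_fraction_nonsevere: 0.11
    nocturnal_fraction_severe: 0.00
    annual_therapy_cost_key: oral_semaglutide
  comparator:
    arm_name: empagliflozin
    delta_hba1c: {mean: -0.79, se: 0.05, significant: true}
    delta_sbp: {mean: -4.34, se: 0.63, significant: false}
    delta_tc: {mean: 4.74, se: 1.57, significant: true}
    delta_hdl: {mean: 3.11, se: 0.34, significant: true}
    delta_bmi: {mean: -1.37, se: 0.09, significant: true}
    delta_egfr: {mean: 0.0, se: 0.0, significant: false}
    nonsevere_hypo_rate: 1.90
    severe_hypo_rate: 0.24
    nocturnal_fraction_nonsevere: 0.13
    nocturnal_fraction_severe: 0.00
    annual_therapy_cost_key: empagliflozin
nma:
  intervention:
    arm_name: oral_semaglutide
    delta_hba1c: {mean: -1.50, se: 0.13, significant: false}
    delta_sbp: {mean: -3.09, se: 1.13, significant: false}
    delta_tc: {mean: 0.0, se: 0.0, significant: false}
    delta_hdl: {mean: 0.0, se: 0.0, significant: false}
    delta_bmi: {mean: -1.50, se: 0.18, significant: true}
    delta_egfr: {mean: 0.0, se: 0.0, significant: false}
    nonsevere_hypo_rate: 0.0
    severe_hypo_rate: 0.0
    nocturnal_fraction_nonsevere: 0.0
    nocturnal_fraction_severe: 0.0
    annual_therapy_cost_key: oral_semaglutide
  comparator:
    arm_name: dulaglutide
    delta_hba1c: {mean: -1.29, se: 0.11, significant: false}
    delta_sbp: {mean: -3.57, se: 1.08, significant: false}
    delta_tc: {mean: 0.0, se: 0.0, significant: false}
    delta_hdl: {mean: 0.0, se: 0.0, significant: false}
    delta_bmi: {mean: -0.73, se: 0.17, significant: true}
    delta_egfr: {mean: 0.0, se: 0.0, significant: false}
    nonsevere_hypo_rate: 0.0
    severe_hypo_rate: 0.0
    nocturnal_fraction_nonsevere: 0.0
    nocturnal_fraction_severe: 0.0
    annual_therapy_cost_key: dulaglutide
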