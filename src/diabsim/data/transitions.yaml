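# Microvascular stage-chain transition tables (annual probabilities,
# forward-only).  These stand in for the reference engine's unpublished
# microvascular sub-models so that every utility-bearing health state is
# reachable; probabilities are user-editable defaults.
# hba1c_rr_per_point multiplies the probability by rr^(HbA1c - 7) per
# %-point of HbA1c above 7%; `gates` multiply when a patient flag is set.
chains:
- name: retinopathy
  states: [none, bdr, pdr, svl]
  transitions:
  - {frm: none, to: bdr, probability: 0.025, hba1c_rr_per_point: 1.10}
  - {frm: bdr, to: pdr, probability: 0.020, hba1c_rr_per_point: 1.10}
  - {frm: pdr, to: svl, probability: 0.030, hba1c_rr_per_point: 1.05}
- name: nephropathy
  states: [none, microalbuminuria, gross_proteinuria, esrd_hemodialysis, esrd_peritoneal, esrd_transplant]
  transitions:
  - {frm: none, to: microalbuminuria, probability: 0.030, hba1c_rr_per_point: 1.08}
  - {frm: microalbuminuria, to: gross_proteinuria, probability: 0.025, hba1c_rr_per_point: 1.08}
  - {frm: gross_proteinuria, to: esrd_hemodialysis, probability: 0.024, hba1c_rr_per_point: 1.05}
  - {frm: gross_proteinuria, to: esrd_peritoneal, probability: 0.0045, hba1c_rr_per_point: 1.05}
  - {frm: gross_proteinuria, to: esrd_transplant, probability: 0.0015, hba1c_rr_per_point: 1.05}
- name: neuropathy
  states: [none, neuropathy]
  transitions:
  - {frm: none, to: neuropathy, probability: 0.020, hba1c_rr_per_point: 1.08}
- name: foot_ulcer
  states: [none, active_ulcer, healed_ulcer]
  transitions:
  - {frm: none, to: active_ulcer, probability: 0.004, hba1c_rr_per_point: 1.05,
     gates: [{flag: neuropathy, multiplier: 5.0}]}
  - {frm: active_ulcer, to: healed_ulcer, probability: 0.40}
- name: macular_edema
  states: [none, macular_edema]
  transitions:
  - {frm: none, to: macular_edema, probability: 0.002, hba1c_rr_per_point: 1.08,
     gates: [{flag: any_retinopathy, multiplier: 5.0}]}
- name: cataract
  states: [none, cataract]
  transitions:
  - {frm: none, to: cataract, probability: 0.010}
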