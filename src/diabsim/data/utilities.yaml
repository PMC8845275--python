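# Health-state utilities and event-based disutilities (published literature
# review values; EQ-5D-preferring).  State utilities are the annual utility
# of a patient whose only complication is that state; the engine combines
# coexisting states by additive decrements from the complication-free
# baseline.  Event disutilities and the per-unit BMI decrement are signed
# (negative).  Alternative-model entries (`lee_*`, `currie_*`,
# `lauridsen_*`) are selected via the simulation config.
baseline_utility: 0.785
state_utilities:
  post_mi: 0.730
  angina: 0.695
  chf: 0.677
  post_stroke: 0.621
  pvd: 0.724
  microalbuminuria: 0.785
  gross_proteinuria: 0.737
  hemodialysis: 0.621
  peritoneal_dialysis: 0.581
  renal_transplant: 0.762
  bdr: 0.745
  pdr: 0.715
  macular_edema: 0.745
  svl: 0.711
  cataract: 0.769
  neuropathy: 0.701
  healed_ulcer: 0.785
  active_ulcer: 0.615
  post_amputation: 0.505
event_disutilities:
  mi_event: -0.055
  stroke_event: -0.164
  amputation_event: -0.280
hypo_disutilities:
  nonsevere_daytime: -0.004
  nonsevere_nocturnal: -0.007
  severe_daytime: -0.057
  severe_nocturnal: -0.062
currie_hypo_disutilities:   # alternative per-event decrements, user-editable
  nonsevere_daytime: -0.0028
  nonsevere_nocturnal: -0.0028
  severe_daytime: -0.0118
  severe_nocturnal: -0.0118
lauridsen_rho: 0.8          # k-th cumulative severe event decremented by rho^(k-1)
bmi_disutility_per_unit: -0.0061
lee_bmi_disutility_per_unit: -0.0038   # alternative BMI model, user-editable
bmi_reference: 25.0
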