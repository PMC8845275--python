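# Complication-related mortality, combined with life-table background
# mortality as independent competing risks: 1 - prod(1 - q_i).
# "fatality:<event tag>" applies in the cycle the event occurs;
# "excess:<state tag>" applies every cycle the chronic state is active.
# Intercept-only logistic form: q = expit(intercept).  User-editable.
equations:
- {outcome: "fatality:mi_event", form: logistic, intercept: -1.7346, coefficients: {}, covariate_centering: {}, source_label: "case fatality 0.15"}
- {outcome: "fatality:stroke_event", form: logistic, intercept: -1.7346, coefficients: {}, covariate_centering: {}, source_label: "case fatality 0.15"}
- {outcome: "fatality:amputation_event", form: logistic, intercept: -2.1972, coefficients: {}, covariate_centering: {}, source_label: "case fatality 0.10"}
- {outcome: "fatality:renal_failure_event", form: logistic, intercept: -2.9444, coefficients: {}, covariate_centering: {}, source_label: "case fatality 0.05"}
- {outcome: "excess:chf", form: logistic, intercept: -2.7515, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.06"}
- {outcome: "excess:post_mi", form: logistic, intercept: -4.5951, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.01"}
- {outcome: "excess:post_stroke", form: logistic, intercept: -3.8918, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.02"}
- {outcome: "excess:hemodialysis", form: logistic, intercept: -1.9924, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.12"}
- {outcome: "excess:peritoneal_dialysis", form: logistic, intercept: -1.9924, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.12"}
- {outcome: "excess:renal_transplant", form: logistic, intercept: -3.4761, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.03"}
- {outcome: "excess:post_amputation", form: logistic, intercept: -3.4761, coefficients: {}, covariate_centering: {}, source_label: "annual excess 0.03"}
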