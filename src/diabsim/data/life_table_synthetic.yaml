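# SYNTHETIC life table (Gompertz form), a stand-in for national age-sex
# mortality tables applied to a type 2 diabetes cohort (mortality is
# roughly 1.6x the general population).  q(age) = min(1, A*exp(B*age));
# male A=7.5e-5, B=0.0896; female hazard scaled by 0.6.  5-year bands
# (mid-band value); ages >= 100 map to q = 1.
rows:
- {age_lo: 18, age_hi: 20, sex: male, q: 0.000412}
- {age_lo: 20, age_hi: 25, sex: male, q: 0.000563}
- {age_lo: 25, age_hi: 30, sex: male, q: 0.000881}
- {age_lo: 30, age_hi: 35, sex: male, q: 0.001380}
- {age_lo: 35, age_hi: 40, sex: male, q: 0.002159}
- {age_lo: 40, age_hi: 45, sex: male, q: 0.003380}
- {age_lo: 45, age_hi: 50, sex: male, q: 0.005290}
- {age_lo: 50, age_hi: 55, sex: male, q: 0.008279}
- {age_lo: 55, age_hi: 60, sex: male, q: 0.012958}
- {age_lo: 60, age_hi: 65, sex: male, q: 0.020282}
- {age_lo: 65, age_hi: 70, sex: male, q: 0.031745}
- {age_lo: 70, age_hi: 75, sex: male, q: 0.049686}
- {age_lo: 75, age_hi: 80, sex: male, q: 0.077768}
- {age_lo: 80, age_hi: 85, sex: male, q: 0.121721}
- {age_lo: 85, age_hi: 90, sex: male, q: 0.190515}
- {age_lo: 90, age_hi: 95, sex: male, q: 0.298191}
- {age_lo: 95, age_hi: 100, sex: male, q: 0.466722}
- {age_lo: 100, age_hi: 130, sex: male, q: 1.0}
- {age_lo: 18, age_hi: 20, sex: female, q: 0.000247}
- {age_lo: 20, age_hi: 25, sex: female, q: 0.000338}
- {age_lo: 25, age_hi: 30, sex: female, q: 0.000529}
- {age_lo: 30, age_hi: 35, sex: female, q: 0.000828}
- {age_lo: 35, age_hi: 40, sex: female, q: 0.001296}
- {age_lo: 40, age_hi: 45, sex: female, q: 0.002028}
- {age_lo: 45, age_hi: 50, sex: female, q: 0.003174}
- {age_lo: 50, age_hi: 55, sex: female, q: 0.004967}
- {age_lo: 55, age_hi: 60, sex: female, q: 0.007775}
- {age_lo: 60, age_hi: 65, sex: female, q: 0.012169}
- {age_lo: 65, age_hi: 70, sex: female, q: 0.019047}
- {age_lo: 70, age_hi: 75, sex: female, q: 0.029812}
- {age_lo: 75, age_hi: 80, sex: female, q: 0.046661}
- {age_lo: 80, age_hi: 85, sex: female, q: 0.073033}
- {age_lo: 85, age_hi: 90, sex: female, q: 0.114309}
- {age_lo: 90, age_hi: 95, sex: female, q: 0.178914}
- {age_lo: 95, age_hi: 100, sex: female, q: 0.280033}
- {age_lo: 100, age_hi: 130, sex: female, q: 1.0}
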