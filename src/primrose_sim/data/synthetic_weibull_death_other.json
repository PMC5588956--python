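{
  "name": "synthetic_death_other",
  "alpha": -6.436697,
  "gamma": 1.4,
  "centering": {
    "age": 50.3
  },
  "coefficients": {
    "age": 0.085,
    "sex_male": 0.3,
    "smoking_current": 0.55,
    "smoking_ex": 0.15,
    "diabetes": 0.4,
    "heavy_drinking": 0.45,
    "smi_schizophrenia": 0.25,
    "smi_bipolar": 0.05,
    "smi_other_psychosis": 0.1
  }
}
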