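{
  "name": "smi_bmi",
  "variant": "bmi",
  "requires_blood_test": false,
  "centering": {
    "age": 50.3,
    "sbp": 128.0,
    "bmi": 28.0,
    "townsend": 3.0
  },
  "coefficients": {
    "age": 0.07,
    "sex_male": 0.45,
    "sbp": 0.012,
    "antihypertensive": 0.25,
    "smoking_current": 0.6,
    "smoking_ex": 0.15,
    "diabetes": 0.55,
    "bmi": 0.045,
    "smi_schizophrenia": 0.35,
    "smi_bipolar": 0.13999999999999999,
    "smi_other_psychosis": 0.21,
    "heavy_drinking": 0.42,
    "depression": 0.21,
    "antidepressant": 0.13999999999999999,
    "fga": 0.21,
    "sga": 0.27999999999999997,
    "townsend": 0.06999999999999999
  },
  "baseline": {
    "alpha": -6.992877,
    "gamma": 1.3
  }
}
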