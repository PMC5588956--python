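{
  "name": "smi_lipid",
  "variant": "lipid",
  "requires_blood_test": true,
  "centering": {
    "age": 50.3,
    "sbp": 128.0,
    "total_chol": 5.4,
    "hdl_chol": 1.3,
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
    "total_chol": 0.2,
    "hdl_chol": -0.45,
    "smi_schizophrenia": 0.25,
    "smi_bipolar": 0.1,
    "smi_other_psychosis": 0.15,
    "heavy_drinking": 0.3,
    "depression": 0.15,
    "antidepressant": 0.1,
    "fga": 0.15,
    "sga": 0.2,
    "townsend": 0.05
  },
  "baseline": {
    "alpha": -7.085944,
    "gamma": 1.3
  }
}
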