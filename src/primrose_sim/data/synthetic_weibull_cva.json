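{
  "name": "synthetic_cva_primary",
  "alpha": -5.503965,
  "gamma": 1.1,
  "centering": {
    "age": 50.3,
    "sbp": 128.0,
    "hdl_chol": 1.3,
    "weight": 80.0,
    "height": 1.7
  },
  "coefficients": {
    "age": 0.055,
    "sex_male": 0.35,
    "sbp": 0.01,
    "antihypertensive": 0.2,
    "hdl_chol": -0.3,
    "on_statin_baseline": -0.25,
    "weight": 0.006,
    "height": -0.8,
    "diabetes": 0.45,
    "smoking_current": 0.5,
    "smoking_ex": 0.12,
    "heavy_drinking": 0.25,
    "smi_schizophrenia": 0.2,
    "smi_bipolar": 0.08,
    "smi_other_psychosis": 0.12,
    "fga": 0.12,
    "sga": 0.15,
    "depression": 0.12,
    "antidepressant": 0.08
  }
}
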