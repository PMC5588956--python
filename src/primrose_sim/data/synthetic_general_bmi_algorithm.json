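{
  "name": "general_bmi",
  "variant": "bmi",
  "requires_blood_test": false,
  "centering": {
    "age": 50.3,
    "sbp": 128.0,
    "bmi": 28.0
  },
  "coefficients": {
    "age": 0.07,
    "sex_male": 0.45,
    "sbp": 0.012,
    "antihypertensive": 0.25,
    "smoking_current": 0.6,
    "smoking_ex": 0.15,
    "diabetes": 0.55,
    "bmi": 0.045
  },
  "baseline": {
    "s0_10": 0.975916
  }
}
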