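{
  "name": "synthetic_secondary_reach",
  "intercept_event": -3.513979,
  "intercept_fatal": -4.862738,
  "coefficients_event": {
    "age": 0.03,
    "sex_male": 0.2,
    "diabetes": 0.4,
    "smoking_current": 0.3,
    "vascular_beds": 0.35,
    "chf": 0.55,
    "af": 0.3,
    "aspirin": -0.1
  },
  "coefficients_fatal": {
    "age": 0.045,
    "sex_male": 0.15,
    "diabetes": 0.35,
    "smoking_current": 0.35,
    "vascular_beds": 0.4,
    "chf": 0.6,
    "af": 0.35,
    "aspirin": -0.1
  },
  "centering": {
    "age": 50.3,
    "vascular_beds": 1.0
  },
  "horizon_months": 20.0
}
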