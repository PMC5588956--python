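{
  "chd": {
    "stable_angina": 0.28,
    "unstable_angina": 0.14,
    "mi": 0.38,
    "surgery": 0.08,
    "unclassified_chd": 0.12
  },
  "cva": {
    "tia": 0.24,
    "haemorrhagic_stroke": 0.11,
    "ischaemic_stroke": 0.52,
    "unspecified_cva": 0.13
  },
  "fatal_chd": 0.102,
  "fatal_cva": 0.065,
  "secondary_nonfatal": {
    "secondary_mi": 0.42,
    "secondary_stroke": 0.58
  },
  "secondary_fatal": {
    "secondary_mi": 0.5,
    "secondary_stroke": 0.5
  }
}
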