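# Synthetic default cost and utility schedules (NOT the published
# supplementary values; constructed to the published structure and
# magnitude). GBP, 2012/13 price year by convention.
costs:
  algorithm_cost_blood: 20.0
  algorithm_cost_no_blood: 19.0
  statin_annual: 21.0
  statin_alteration_annual: 10.0
  event_costs:
    stable_angina:
      acute: 2751.0
      subsequent: 312.0
    unstable_angina:
      acute: 3862.0
      subsequent: 412.0
    mi:
      acute: 4862.0
      subsequent: 688.0
    surgery:
      acute: 9583.0
      subsequent: 688.0
    unclassified_chd:
      acute: 4497.0
      subsequent: 494.0
    tia:
      acute: 1532.0
      subsequent: 173.0
    haemorrhagic_stroke:
      acute: 10452.0
      subsequent: 1130.0
    ischaemic_stroke:
      acute: 9500.0
      subsequent: 1130.0
    unspecified_cva:
      acute: 7205.0
      subsequent: 830.0
    secondary_mi:
      acute: 4862.0
      subsequent: 688.0
    secondary_stroke:
      acute: 9500.0
      subsequent: 1130.0
    fatal_chd:
      acute: 1521.0
    fatal_cva:
      acute: 4092.0
utilities:
  base_utility: 0.865
  decrements:
    stable_angina: 0.0412
    unstable_angina: 0.077
    mi: 0.0626
    tia: 0.0302
    haemorrhagic_stroke: 0.1171
    ischaemic_stroke: 0.1171
    surgery: 0.0626
    unclassified_chd: 0.0576
    unspecified_cva: 0.0931
    secondary_mi: 0.0626
    secondary_stroke: 0.1171
  alt_utilities:
    relapse: 0.479
    eps: 0.604
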