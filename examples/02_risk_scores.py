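"""Score a cohort with the four risk algorithms and classify at the 10%
ten-year CVD risk threshold.

Each algorithm is a linear predictor over baseline covariates with a
baseline survival at 10 years; a patient scoring strictly over the
threshold is 'high risk' and eligible for statin therapy.  The shipped
coefficient sets are synthetic, constructed so the SMI-specific BMI
algorithm classifies the most patients high risk and the general BMI
algorithm the fewest, matching the published pattern.
"""

from primrose_sim import (ThresholdPolicy, default_algorithms,
                          default_cohort_spec, generate_cohort, score_cohort)

cohort = generate_cohort(default_cohort_spec(n=1000, seed=42))
policy = ThresholdPolicy(0.10)

print(f"{'algorithm':<16} {'mean 10y risk':>14} {'high risk':>10} {'blood test':>11}")
for name, alg in default_algorithms().items():
    scored = score_cohort(cohort, alg, policy)
    n_high = int((scored["risk_class"] == "high").sum())
    print(f"{name:<16} {scored['risk'].mean():>13.1%} {n_high:>10} "
          f"{'yes' if alg.requires_blood_test else 'no':>11}")
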