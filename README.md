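# primrose-sim

Patient-level cost-effectiveness microsimulation of cardiovascular (CVD)
risk algorithms and statin prescribing for people with severe mental
illness (SMI) in UK primary care.

People with SMI (schizophrenia, bipolar disorder, other non-organic
psychoses) carry a substantially elevated CVD risk, and bespoke risk
algorithms (PRIMROSE, in lipid and BMI variants) exist alongside
general-population scores.  This package implements the economic model
used to compare them: each simulated patient is scored with a 10-year CVD
risk algorithm at baseline, patients scoring over a threshold (e.g. 10%)
start statins, and everyone then cycles through a 10-year annual
state-transition model of primary CVD events, secondary (recurrent)
events, CVD death and other-cause death, accruing costs and
quality-adjusted life years (QALYs).  Five arms are compared — general
lipid, general BMI, SMI-specific lipid, SMI-specific BMI, and no
algorithm — by net monetary benefit (NMB), with deterministic scenario
analyses and a two-level probabilistic sensitivity analysis (PSA)
summarised as cost-effectiveness acceptability curves (CEACs).

The intended audience is health-economic modellers and methods
researchers who need a transparent, reproducible, scriptable version of
this class of model.

## Model core

* **Risk scoring** — 10-year risk `1 − S₀(10)^exp(LP)` (proportional
  hazards) or `1 − exp(−exp(α + LP)·10^γ)` (Weibull), with
  `LP = Σ βᵢ(xᵢ − cᵢ)` over baseline covariates; classification is
  strictly `risk > threshold`.
* **Transitions** — Weibull survival `S(t) = exp(−exp(α+LP)·t^γ)` for
  primary CHD, primary stroke and non-CVD death, giving cycle
  probabilities `p_t = 1 − S(t)/S(t−1)`; registry-style 20-month
  equations for secondary events converted to annual probabilities via
  `p = 1 − exp(−rt)`; statins multiply primary probabilities by the
  Cochrane relative risks (0.73 CHD, 0.78 stroke) for new prescriptions.
* **Events** — realized when the patient-specific probability exceeds a
  uniform draw; severity resolved by substate tables (angina/MI/surgery/…,
  TIA/stroke types); death states absorbing.
* **Economics** — algorithm cost £20 (blood test) / £19 (none), statins
  £21/year, per-substate acute and maintenance event costs; utility 0.865
  (stable SMI) minus persistent event decrements; everything discounted at
  3.5%/year, annuity-due; `NMB = λ·QALYs − costs`.
* **Uncertainty** — one-way scenarios (doubled cost blocks, utilities
  0.479/0.604, RRs 0.8/0.89, 50% adherence) and an outer/inner-loop PSA.

The true coefficient tables of the published algorithms are not publicly
available, so the package ships clearly labelled **synthetic** default
coefficient sets (`src/primrose_sim/data/synthetic_*`) that reproduce the
published qualitative behaviour and event magnitudes; all coefficient
sets, costs and utilities are user-replaceable JSON/YAML.

## Worked example

```python
from primrose_sim import default_config, run_all

config = default_config(n=1000, seed=42)
run = run_all(config, seed=42, n_iterations=20)
for _, row in run.incrementals.iterrows():
    if row["arm"] != "none":
        print(f"{row['arm']:<16} saves £{-row['d_cost_disc']:,.0f} and gains "
              f"{row['d_qalys_disc']:.1f} QALYs per 1000 patients vs no algorithm")
```

prints

```
general_lipid    saves £82,513 and gains 13.7 QALYs per 1000 patients vs no algorithm
smi_lipid        saves £75,776 and gains 12.6 QALYs per 1000 patients vs no algorithm
general_bmi      saves £70,036 and gains 11.6 QALYs per 1000 patients vs no algorithm
smi_bmi          saves £95,999 and gains 16.3 QALYs per 1000 patients vs no algorithm
```

i.e. every algorithm arm dominates no algorithm (cheaper *and* more
effective, because the low-cost statins prevent high-cost CVD events),
and the SMI-specific BMI algorithm — which needs no blood test — does
best, mirroring the published finding.  The `examples/` directory has one
short script per capability (cohort generation, risk scoring, the
five-arm run, sensitivity/PSA), and the `primrose-sim` CLI exposes
`generate`, `score`, `run` and `psa` for shell use.

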