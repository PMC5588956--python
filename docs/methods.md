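# Methods

## Model overview

The package implements a patient-level decision-tree + state-transition
model for primary CVD prevention in a severe mental illness (SMI)
population.  At baseline each patient's 10-year CVD risk is computed with
one of four algorithms (general-population lipid/BMI, SMI-specific
lipid/BMI); patients strictly over the risk threshold (default 10%) and
not already on statins receive a new statin prescription; patients
already on statins continue (intensified if baseline total cholesterol
> 5 mmol/L or total/HDL ratio > 4, tested once at entry).  All patients
then run through 10 one-year cycles of a four-state machine (healthy →
post-primary-event → CVD death / other-cause death), and the five
scenario arms (four algorithms plus no algorithm) are compared on
discounted costs, QALYs and net monetary benefit.

Assumptions carried by the model structure:

* events occur at the start of a cycle; at most one event per patient
  per cycle; death states are absorbing;
* secondary (recurrent) CVD risk applies only from the cycle *after* the
  first primary event, and does not reset after a secondary event;
* statin status is fixed for the full horizon once assigned, and the
  statin benefit is constant over the 10 years;
* baseline covariates do not drift across cycles (no BP/weight
  trajectories); time enters the hazards as time since model entry, with
  age a baseline covariate.

## Transition probabilities

Primary CHD, primary stroke and other-cause death use Weibull
proportional-hazards survival models
`S(t) = exp(−exp(α + LP)·t^γ)`, `LP = Σ βᵢ(xᵢ − cᵢ)`, with the cycle-t
conditional probability `p_t = 1 − S(t)/S(t−1)`.  Within a cycle the
draw order is: other-cause death, then (if healthy) primary CHD, then
primary stroke, then (if post-primary) fatal secondary, then non-fatal
secondary.  The source material lists the five possibilities without an
order; the chosen order resolves competing events deterministically and
is isolated in the engine.

Secondary events use two registry-style 20-month risk equations (any
next CVD event; fatal CVD event) with single-vascular-bed / no-CHF /
no-AF / no-aspirin fixed assumptions.  The published equations' link
function is not stated; this implementation uses a logistic link,
isolated in `transitions.reach_20_month_probability` so a user-supplied
table with a different link can replace one function.  The 20-month
probabilities are converted to 12 months by the constant-rate identity
`p = 1 − exp(−rt)`, and the non-fatal probability is the excess of the
any-event over the fatal probability.

Statins multiply the primary CHD/stroke probabilities of newly
prescribed patients by relative risks 0.73 / 0.78; partial adherence a
gives the effective multiplier `1 − a·(1 − RR)`.  Patients already on
statins at baseline get no further reduction: their baseline-statin flag
is a covariate of the survival models, so their risk is already
conditioned on treatment.

Event severity is allocated from categorical substate tables (CHD:
stable/unstable angina, MI, surgery, unclassified; stroke: TIA,
haemorrhagic, ischaemic, unspecified), with class-specific fatal
fractions applied first; fatal secondary events split equally between MI
and stroke.

## Synthetic cohort generator

The generator reproduces the *marginal* baseline distributions published
for the eligible UK primary-care SMI population (N = 33 026): truncated
normals for continuous covariates (age on [30, 74], SBP [70, 250], total
cholesterol [1, 15], HDL [0.4, 5], weight [30, 250], height [1.2, 2.2];
truncation by redraw, never clamping) and published proportions for
discrete covariates (categorical proportions are computed from the
published counts so each block sums to one exactly).  Because truncation
shifts and shrinks raw normal moments (age drawn naively would average
~50.9 instead of 50.3), the parent normal parameters are moment-matched
numerically so the truncated marginal hits the published mean and SD.
BMI is derived from weight and height to keep the three consistent;
calendar year is drawn normal(2007.7, 3.5) and rounded.

Covariates are drawn independently — only marginals are published and no
correlation structure is invented.  An optional Gaussian copula accepts
a user correlation matrix over the continuous block.  Multiple
imputation belongs to the original data pipeline, not this generator:
synthetic records are complete by construction.  Consequences for
interpretation: passing tests show the machinery is correct under
realistic marginals, but real SMI cohorts have correlated risk factors
(e.g. weight–height, age–SBP), so absolute event counts and costs from
the synthetic defaults are indicative magnitudes, not predictions.

## Synthetic default parameter sets

The published supplementary coefficient tables (risk algorithms,
transition models, substate proportions, event costs, utility
decrements) are not publicly available.  The package therefore ships
synthetic default sets, labelled `synthetic_*` in `primrose_sim/data/`,
constructed in two steps: plausible per-unit coefficients were fixed
from domain knowledge, then the baseline parameters (S₀(10) or Weibull
intercepts, secondary-equation intercepts) were solved numerically so
that, on a large synthetic cohort:

* the four algorithms classify high-risk fractions of 26.8% / 24.1% /
  22.2% / 32.6% (general lipid / SMI lipid / general BMI / SMI BMI) at
  the 10% threshold, reproducing the published ordering — SMI-BMI most,
  general-BMI fewest;
* the no-algorithm arm's expected 10-year event counts per 1000 match
  the published magnitudes (~97 primary CHD, ~116 primary stroke, ~17
  non-fatal and ~8 fatal secondary events, ~119 other-cause deaths).

Fatal fractions (10.2% of primary CHD, 6.5% of primary stroke) are the
ratios implied by the published event table.  Event costs and utility
decrements (angina 0.0412, MI 0.0626, stroke 0.1171, TIA 0.0302;
surgery = MI; composites as weighted averages of their components) are
synthetic placeholders of realistic magnitude; the statin alteration
cost delta defaults to £10/year.  Reproducing the published absolute
costs/QALYs is explicitly not a goal — those depend on the real cohort
and the unpublished tables — but the defaults land within ~10% of the
published event-cost total.

## Economics

Annuity-due discounting at 3.5%/year: cycle-t flows are divided by
1.035^(t−1), so cycle-1 flows (and the once-only algorithm cost) are
undiscounted, consistent with events at cycle start; the exponent
convention is a config switch.  Statin costs accrue each alive cycle;
event costs as an acute-year cost plus a maintenance cost every later
alive year; fatal events carry a one-off cost.  Utility is the stable-SMI
baseline 0.865 minus the sum of all active decrements, floored at zero
(multiple-event decrements are additive — the source handles single
decrements only); dead cycles contribute zero.  CEAC ties are split
equally across arms.

## Randomness and reproducibility

All event draws come from one uniform array indexed (patient, cycle,
draw-slot), generated by a PCG64 stream seeded with the (master seed,
replicate) pair.  The array never depends on the scenario arm, so all
arms see identical uniforms — common random numbers — and a treated
arm with RR = 1 reproduces the no-algorithm arm exactly.  The PSA
samples outer parameter vectors from streams seeded (seed, 7919, k) and
uses event replicate k·n_inner + i for inner iteration i, making every
result deterministic in the master seed.

## Sensitivity analysis

One-way scenarios mutate exactly one assumption (each a pure transform
of the config): doubled all/statin/algorithm/event costs, SMI utility
0.479 (relapse) or 0.604 (extrapyramidal symptoms), statin RRs at the
upper CIs (0.8 / 0.89), 50% adherence.  The PSA follows the standard
two-level design for stochastic patient-level models: the full design is
1000 outer × 100 inner loops, with each outer value the mean of its
inner loop.  Default priors: gamma for costs with SD equal to the mean
(shape 1) where no CI exists; beta (SD 0.05) for the base utility;
lognormal for the statin RRs with log-SD from the published 95% CIs
(0.67–0.80 CHD, 0.68–0.89 stroke); normal (SD 0.05) for the Weibull
intercepts.  Risk-algorithm and transition-model coefficients are
sampled independently; in reality both were estimated from the same
source data and are correlated — a known limitation.

## Problem sizes used

The shipped analyses and checks use 1000 patients × 10 cycles × 5 arms
for base-case runs (20 event-seed replications averaged where a mean is
reported), 10⁴–10⁵ draws for distributional checks, and a 50 × 20 (or
20 × 10) scaled PSA; the full 1000 × 100 PSA is available through
`run_psa`/the CLI and simply takes proportionally longer (the package's
own choice of demonstration scale).

## Known limitations

* Coefficients are synthetic stand-ins; absolute outputs are
  magnitude-calibrated, not validated predictions.
* Independent covariates understate risk concentration in the tails.
* No half-cycle correction (events at cycle start by construction), no
  statin discontinuation/titration dynamics, no time-varying covariates,
  no value-of-information analysis.
* A fatal secondary event cannot occur in the cycle of the primary
  event (secondary risk starts the next cycle).
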