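"""Deterministic scenario analyses and two-level probabilistic sensitivity
analysis (PSA).

One-way scenarios mutate a single assumption of the base configuration
(doubled cost blocks, lower SMI utility, weaker statin effect, 50%
adherence) and re-run the full five-arm analysis; mutations are pure — the
base configuration object is never modified.

The PSA is the standard two-level design for patient-level models: outer
loops draw one parameter vector from the priors, inner loops re-run the
stochastic patient simulation under that vector with fresh event seeds,
and the outer-loop value is the inner-loop mean.  Default priors follow
health-economics convention where the source gave no distribution: gamma
for costs with SD equal to the mean (shape 1), beta for utilities,
lognormal for relative risks with CI-derived log-SD, normal for survival
intercepts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .economics import EconomicResult, aggregate
from .engine import draw_uniforms, simulate_arm
from .risk import ARM_NAMES
from .config import RunConfig

__all__ = [
    "ScenarioModifier", "PsaPrior", "PsaSampleSet",
    "standard_scenarios", "one_way_suite", "mean_arm_results",
    "default_priors", "sample_psa", "run_psa",
]


# ---------------------------------------------------------------------------
# One-way scenarios

@dataclass(frozen=True)
class ScenarioModifier:
    """A named pure transform of the base configuration."""

    name: str
    description: str
    apply: callable

    def __call__(self, config: RunConfig) -> RunConfig:
        out = self.apply(config)
        if out is config:
            raise ValueError(f"scenario {self.name!r} must return a new config")
        return out


def _scale_event_costs(costs, factor: float) -> dict:
    return {k: {kk: vv * factor for kk, vv in v.items()} for k, v in costs.event_costs.items()}


def _double_all_costs(cfg: RunConfig) -> RunConfig:
    c = cfg.costs
    new = dataclasses.replace(
        c,
        algorithm_cost_blood=c.algorithm_cost_blood * 2,
        algorithm_cost_no_blood=c.algorithm_cost_no_blood * 2,
        statin_annual=c.statin_annual * 2,
        statin_alteration_annual=c.statin_alteration_annual * 2,
        event_costs=_scale_event_costs(c, 2.0),
    )
    return cfg.replace(costs=new)


def _double_statin_costs(cfg: RunConfig) -> RunConfig:
    c = cfg.costs
    return cfg.replace(costs=dataclasses.replace(
        c, statin_annual=c.statin_annual * 2,
        statin_alteration_annual=c.statin_alteration_annual * 2))


def _double_algorithm_costs(cfg: RunConfig) -> RunConfig:
    c = cfg.costs
    return cfg.replace(costs=dataclasses.replace(
        c, algorithm_cost_blood=c.algorithm_cost_blood * 2,
        algorithm_cost_no_blood=c.algorithm_cost_no_blood * 2))


def _double_event_costs(cfg: RunConfig) -> RunConfig:
    return cfg.replace(costs=dataclasses.replace(
        cfg.costs, event_costs=_scale_event_costs(cfg.costs, 2.0)))


def _set_base_utility(value: float):
    def apply(cfg: RunConfig) -> RunConfig:
        return cfg.replace(utilities=dataclasses.replace(cfg.utilities, base_utility=value))
    return apply


def _rr_upper_ci(cfg: RunConfig) -> RunConfig:
    return cfg.replace(effects=dataclasses.replace(cfg.effects, rr_chd=0.8, rr_stroke=0.89))


def _half_adherence(cfg: RunConfig) -> RunConfig:
    return cfg.replace(effects=dataclasses.replace(cfg.effects, adherence=0.5))


def standard_scenarios() -> list[ScenarioModifier]:
    """The one-way deterministic scenario list, base case first."""
    return [
        ScenarioModifier("base_case", "all parameters at their means", lambda c: c.replace()),
        ScenarioModifier("all_costs_x2", "all costs doubled", _double_all_costs),
        ScenarioModifier("statin_costs_x2", "statin treatment costs doubled", _double_statin_costs),
        ScenarioModifier("algorithm_costs_x2", "risk-algorithm costs doubled", _double_algorithm_costs),
        ScenarioModifier("event_costs_x2", "CVD event costs doubled", _double_event_costs),
        ScenarioModifier("utility_relapse", "SMI utility 0.479 (relapse)", _set_base_utility(0.479)),
        ScenarioModifier("utility_eps", "SMI utility 0.604 (extrapyramidal symptoms)", _set_base_utility(0.604)),
        ScenarioModifier("rr_upper_ci", "statin RR at upper CI (0.8 CHD, 0.89 stroke)", _rr_upper_ci),
        ScenarioModifier("adherence_50", "50% statin adherence", _half_adherence),
    ]


def _mean_results(results: list[EconomicResult]) -> EconomicResult:
    """Field-wise mean of arm results over event-seed replications."""
    first = results[0]
    numeric = [f.name for f in dataclasses.fields(EconomicResult)
               if f.name not in ("arm", "n_patients", "horizon", "event_tally")]
    means = {name: float(np.mean([getattr(r, name) for r in results])) for name in numeric}
    keys = set().union(*(r.event_tally for r in results))
    tally = {k: float(np.mean([r.event_tally.get(k, 0) for r in results])) for k in keys}
    return EconomicResult(arm=first.arm, n_patients=first.n_patients,
                          horizon=first.horizon, event_tally=tally, **means)


def mean_arm_results(cohort: pd.DataFrame, config: RunConfig, seed: int,
                     n_iterations: int = 1, arms=ARM_NAMES) -> dict[str, EconomicResult]:
    """Run every arm ``n_iterations`` times with common random numbers and
    return the replication-mean result per arm."""
    per_arm: dict[str, list[EconomicResult]] = {arm: [] for arm in arms}
    for r in range(n_iterations):
        uniforms = draw_uniforms(len(cohort), seed, r, config.horizon)
        for arm in arms:
            sim = simulate_arm(cohort, arm, config, seed, replicate=r, uniforms=uniforms)
            per_arm[arm].append(aggregate(sim, config.costs, config.utilities,
                                          config.discount_rate))
    return {arm: _mean_results(v) for arm, v in per_arm.items()}


def one_way_suite(base_config: RunConfig, cohort: pd.DataFrame, seed: int,
                  n_iterations: int = 5000,
                  scenarios: list[ScenarioModifier] | None = None
                  ) -> list[tuple[ScenarioModifier, dict[str, EconomicResult]]]:
    """Run the one-way deterministic scenario suite.

    Each scenario re-runs all five arms ``n_iterations`` times (the same
    event seeds in every scenario, so differences are attributable to the
    mutation) and reports replication means.
    """
    scenarios = scenarios if scenarios is not None else standard_scenarios()
    out = []
    for scen in scenarios:
        cfg = scen(base_config)
        out.append((scen, mean_arm_results(cohort, cfg, seed, n_iterations)))
    return out


# ---------------------------------------------------------------------------
# PSA priors

@dataclass(frozen=True)
class PsaPrior:
    """A sampling distribution for one configuration parameter.

    ``path`` is a dot path into :class:`RunConfig` (dict keys allowed, e.g.
    ``costs.event_costs.mi.acute``).  Families: ``gamma`` and ``beta`` are
    moment-matched from (mean, sd); ``lognormal`` takes the mean and a 95%
    CI (log-SD derived from the CI width); ``normal`` takes (mean, sd).
    ``sd = 0`` makes any family degenerate at the mean.
    """

    path: str
    family: str
    mean: float
    sd: float = 0.0
    ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family not in ("gamma", "beta", "lognormal", "normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.sd < 0:
            raise ValueError("prior SD must be >= 0")
        if self.family == "beta" and not 0.0 <= self.mean <= 1.0:
            raise ValueError("beta prior mean must be in [0,1]")
        if self.family == "beta" and self.sd > 0 and self.sd ** 2 >= self.mean * (1 - self.mean):
            raise ValueError("beta prior SD too large for its mean")
        if self.family == "lognormal" and self.ci is None and self.sd == 0:
            # degenerate lognormal allowed
            pass

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "lognormal":
            if self.ci is None:
                return self.mean
            lo, hi = self.ci
            sigma = log(hi / lo) / (2 * 1.959963984540054)
            if sigma == 0:
                return self.mean
            return float(np.exp(rng.normal(log(self.mean), sigma)))
        if self.sd == 0:
            return self.mean
        if self.family == "gamma":
            shape = (self.mean / self.sd) ** 2
            scale = self.sd ** 2 / self.mean
            return float(rng.gamma(shape, scale))
        if self.family == "beta":
            nu = self.mean * (1 - self.mean) / self.sd ** 2 - 1
            a, b = self.mean * nu, (1 - self.mean) * nu
            return float(rng.beta(a, b))
        return float(rng.normal(self.mean, self.sd))


def _set_path(config: RunConfig, path: str, value: float) -> RunConfig:
    """Return a new config with the dotted ``path`` set to ``value``."""
    parts = path.split(".")

    def rebuild(obj, parts):
        head, rest = parts[0], parts[1:]
        if not rest:
            new_leaf = value
        else:
            child = obj[head] if isinstance(obj, dict) else getattr(obj, head)
            new_leaf = rebuild(child, rest)
        if isinstance(obj, dict):
            new = dict(obj)
            if head not in new:
                raise KeyError(f"no key {head!r} on PSA path {path!r}")
            new[head] = new_leaf
            return new
        if dataclasses.is_dataclass(obj):
            if head not in {f.name for f in dataclasses.fields(obj)}:
                raise AttributeError(f"no field {head!r} on PSA path {path!r}")
            return dataclasses.replace(obj, **{head: new_leaf})
        raise TypeError(f"cannot descend into {type(obj)} at {head!r} of {path!r}")

    return rebuild(config, parts)


def default_priors(config: RunConfig) -> list[PsaPrior]:
    """Default prior set over the base configuration.

    Costs use the SD-equal-to-mean gamma convention (shape 1); the base SMI
    utility a beta with SD 0.05; statin relative risks lognormals on the
    published 95% CIs; Weibull intercepts of the three survival models
    normals with SD 0.05.
    """
    c = config.costs
    priors = [
        PsaPrior("costs.algorithm_cost_blood", "gamma", c.algorithm_cost_blood,
                 c.algorithm_cost_blood),
        PsaPrior("costs.algorithm_cost_no_blood", "gamma", c.algorithm_cost_no_blood,
                 c.algorithm_cost_no_blood),
        PsaPrior("costs.statin_annual", "gamma", c.statin_annual, c.statin_annual),
        PsaPrior("costs.statin_alteration_annual", "gamma", c.statin_alteration_annual,
                 c.statin_alteration_annual),
        PsaPrior("utilities.base_utility", "beta", config.utilities.base_utility, 0.05),
        PsaPrior("effects.rr_chd", "lognormal", 0.73, ci=(0.67, 0.80)),
        PsaPrior("effects.rr_stroke", "lognormal", 0.78, ci=(0.68, 0.89)),
        PsaPrior("chd_model.alpha", "normal", config.chd_model.alpha, 0.05),
        PsaPrior("cva_model.alpha", "normal", config.cva_model.alpha, 0.05),
        PsaPrior("death_model.alpha", "normal", config.death_model.alpha, 0.05),
    ]
    for sub, entry in c.event_costs.items():
        for kind, val in entry.items():
            if val > 0:
                priors.append(PsaPrior(f"costs.event_costs.{sub}.{kind}", "gamma", val, val))
    return priors


def sample_psa(priors: list[PsaPrior], seed_or_rng) -> dict[str, float]:
    """One parameter vector: a draw from each prior, keyed by path."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return {p.path: p.sample(rng) for p in priors}


@dataclass
class PsaSampleSet:
    """Outer-loop parameter draws with inner-loop mean results per arm."""

    parameters: pd.DataFrame          # one row per outer draw, one column per path
    results: pd.DataFrame             # columns: draw, arm, cost, qaly (discounted)
    seed: int
    n_inner: int

    @property
    def n_outer(self) -> int:
        return len(self.parameters)


def run_psa(cohort: pd.DataFrame, config: RunConfig, priors: list[PsaPrior],
            n_outer: int = 1000, n_inner: int = 100, seed: int = 0,
            arms=ARM_NAMES) -> PsaSampleSet:
    """Two-level PSA.

    Outer draw k samples a parameter vector (its own RNG stream derived
    from the master seed); inner iteration i re-runs every arm with event
    replicate ``k·n_inner + i`` — identical uniforms across arms, fresh
    across inner iterations.  Fully deterministic in ``seed``.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    param_rows, result_rows = [], []
    for k in range(n_outer):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 7919, k)))
        draws = sample_psa(priors, rng)
        cfg = config
        for path, value in draws.items():
            cfg = _set_path(cfg, path, value)
        param_rows.append(draws)
        sums = {arm: np.zeros(2) for arm in arms}
        for i in range(n_inner):
            replicate = k * n_inner + i
            uniforms = draw_uniforms(len(cohort), seed, replicate, cfg.horizon)
            for arm in arms:
                sim = simulate_arm(cohort, arm, cfg, seed, replicate=replicate,
                                   uniforms=uniforms)
                res = aggregate(sim, cfg.costs, cfg.utilities, cfg.discount_rate)
                sums[arm] += (res.cost_total_disc, res.qalys_disc)
        for arm in arms:
            cost, qaly = sums[arm] / n_inner
            result_rows.append((k, arm, float(cost), float(qaly)))
    return PsaSampleSet(
        parameters=pd.DataFrame(param_rows),
        results=pd.DataFrame(result_rows, columns=["draw", "arm", "cost", "qaly"]),
        seed=seed, n_inner=n_inner)
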