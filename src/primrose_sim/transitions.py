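"""Annual transition probabilities for the state-transition model.

Primary coronary (CHD) and cerebrovascular (CVA) events, and death from
non-CVD causes, come from patient-level Weibull survival models

    S(t) = exp(−exp(alpha + LP) · t^gamma),    t in years from model entry,

from which the probability of an event in cycle t conditional on reaching it
is p_t = 1 − S(t)/S(t−1).  Secondary (recurrent) events after a first CVD
event come from registry-style 20-month risk equations (one for any next
event, one for a fatal event), converted to annual probabilities through the
constant-rate identity p = 1 − exp(−r·t).  Statin therapy acts as a relative
risk multiplier on the primary event probabilities of the newly treated.

Event severity is resolved by categorical substate tables (angina / MI /
surgery / ... for CHD; TIA / stroke types for CVA) so that costs and utility
decrements can be attached per substate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import linear_predictor_frame

__all__ = [
    "WeibullSurvivalModel",
    "ReachModel",
    "SubstateTable",
    "EffectParameters",
    "cycle_probability",
    "cycle_probability_frame",
    "apply_statin_effect",
    "convert_period_probability",
    "reach_20_month_probability",
    "secondary_annual_risks",
    "allocate_substate",
    "other_cause_death_probability",
    "load_weibull_model",
    "load_reach_model",
    "default_transition_models",
]


class TransitionConfigError(ValueError):
    """Invalid transition-model configuration."""


@dataclass(frozen=True)
class WeibullSurvivalModel:
    """Weibull PH survival model S(t) = exp(−exp(alpha+LP)·t^gamma)."""

    name: str
    alpha: float
    gamma: float
    coefficients: dict[str, float] = field(default_factory=dict)
    centering: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.gamma <= 0:
            raise TransitionConfigError(f"{self.name}: Weibull shape must be > 0, got {self.gamma}")

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        return linear_predictor_frame(cohort, self.coefficients, self.centering, self.name)

    def survival(self, lp, t) -> np.ndarray:
        lam = np.exp(self.alpha + np.asarray(lp, dtype=float))
        return np.exp(-lam * np.asarray(t, dtype=float) ** self.gamma)

    def to_dict(self) -> dict:
        return {"name": self.name, "alpha": self.alpha, "gamma": self.gamma,
                "centering": dict(self.centering), "coefficients": dict(self.coefficients)}

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullSurvivalModel":
        return cls(name=d["name"], alpha=float(d["alpha"]), gamma=float(d["gamma"]),
                   coefficients={k: float(v) for k, v in d.get("coefficients", {}).items()},
                   centering={k: float(v) for k, v in d.get("centering", {}).items()})


def cycle_probability(model: WeibullSurvivalModel, patient, t: int) -> float:
    """Probability of the event in cycle t given event-free survival to t−1."""
    frame = patient if isinstance(patient, pd.DataFrame) else pd.DataFrame([dict(patient)])
    return float(cycle_probability_frame(model, frame, t)[0])


def cycle_probability_frame(model: WeibullSurvivalModel, cohort: pd.DataFrame, t: int) -> np.ndarray:
    """Vectorized p_t = 1 − S(t)/S(t−1) over a cohort."""
    if t < 1:
        raise ValueError(f"cycle year must be >= 1, got {t}")
    lp = model.linear_predictor(cohort)
    lam = np.exp(model.alpha + lp)
    # S(t)/S(t−1) computed in log space for numerical safety
    return 1.0 - np.exp(-lam * (t ** model.gamma - (t - 1) ** model.gamma))


def other_cause_death_probability(model: WeibullSurvivalModel, patient, t: int) -> float:
    """Annual probability of death from non-CVD causes; same Weibull form."""
    return cycle_probability(model, patient, t)


@dataclass(frozen=True)
class EffectParameters:
    """Statin treatment effect: Cochrane relative risks with adherence mixing.

    RR 0.73 for CHD and 0.78 for stroke; partial adherence a gives the
    effective multiplier 1 − a·(1 − RR)."""

    rr_chd: float = 0.73
    rr_stroke: float = 0.78
    adherence: float = 1.0

    def __post_init__(self):
        for rr in (self.rr_chd, self.rr_stroke):
            if not 0.0 < rr <= 1.0:
                raise TransitionConfigError(f"relative risk must be in (0,1], got {rr}")
        if not 0.0 <= self.adherence <= 1.0:
            raise TransitionConfigError(f"adherence must be in [0,1], got {self.adherence}")

    def effective_rr(self) -> tuple[float, float]:
        a = self.adherence
        return (1.0 - a * (1.0 - self.rr_chd), 1.0 - a * (1.0 - self.rr_stroke))


def apply_statin_effect(p_chd, p_cva, plan, eff: EffectParameters):
    """Scale primary event probabilities by the effective RR when the plan
    newly prescribes statins; otherwise pass through unchanged."""
    if not getattr(plan, "rr_applies", plan):
        return p_chd, p_cva
    rr_chd, rr_cva = eff.effective_rr()
    return p_chd * rr_chd, p_cva * rr_cva


def convert_period_probability(p, from_months: float, to_months: float):
    """Re-express a probability over a different period at constant rate:
    r = −ln(1−p)/from_months; return 1 − exp(−r·to_months)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability must be in [0,1) for period conversion")
    if from_months <= 0 or to_months <= 0:
        raise ValueError("periods must be positive")
    out = 1.0 - (1.0 - p) ** (to_months / from_months)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ReachModel:
    """Registry-style recurrent-event risk equations over a 20-month horizon.

    Two logistic equations — probability of a next CVD event and of a fatal
    CVD event — on patient covariates.  Number of vascular beds, CHF, AF and
    aspirin use are unavailable in the source data and fixed by assumption
    (one bed, all three absent), so their coefficients never contribute.
    The country adjustment is omitted (UK is the reference level).
    """

    name: str
    intercept_event: float
    intercept_fatal: float
    coefficients_event: dict[str, float] = field(default_factory=dict)
    coefficients_fatal: dict[str, float] = field(default_factory=dict)
    centering: dict[str, float] = field(default_factory=dict)
    horizon_months: float = 20.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept_event": self.intercept_event,
            "intercept_fatal": self.intercept_fatal,
            "coefficients_event": dict(self.coefficients_event),
            "coefficients_fatal": dict(self.coefficients_fatal),
            "centering": dict(self.centering),
            "horizon_months": self.horizon_months,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReachModel":
        return cls(
            name=d["name"],
            intercept_event=float(d["intercept_event"]),
            intercept_fatal=float(d["intercept_fatal"]),
            coefficients_event={k: float(v) for k, v in d.get("coefficients_event", {}).items()},
            coefficients_fatal={k: float(v) for k, v in d.get("coefficients_fatal", {}).items()},
            centering={k: float(v) for k, v in d.get("centering", {}).items()},
            horizon_months=float(d.get("horizon_months", 20.0)),
        )


def reach_20_month_probability(intercept: float, lp) -> np.ndarray:
    """Link from linear predictor to horizon probability: logistic.

    The published equations do not state their link; the choice is isolated
    here so a user-supplied coefficient table with a different link can
    override a single function.
    """
    out = expit(intercept + np.asarray(lp, dtype=float))
    return float(out) if out.ndim == 0 else out


def secondary_annual_risks(patient_state, reach: ReachModel):
    """(p_nonfatal, p_fatal) annual secondary-event probabilities.

    The 20-month probabilities from the two equations are converted to
    12 months; the fatal probability is carved out of the overall next-event
    probability, so p_nonfatal = max(p_event − p_fatal, 0).
    """
    frame = patient_state if isinstance(patient_state, pd.DataFrame) else pd.DataFrame([dict(patient_state)])
    p_event, p_fatal = secondary_annual_risks_frame(frame, reach)
    p_nonfatal = np.maximum(p_event - p_fatal, 0.0)
    if len(frame) == 1:
        return float(p_nonfatal[0]), float(p_fatal[0])
    return p_nonfatal, p_fatal


def secondary_annual_risks_frame(cohort: pd.DataFrame, reach: ReachModel
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (p_any_event_12m, p_fatal_12m) over a cohort."""
    lp_e = linear_predictor_frame(cohort, reach.coefficients_event, reach.centering, reach.name)
    lp_f = linear_predictor_frame(cohort, reach.coefficients_fatal, reach.centering, reach.name)
    p20_e = reach_20_month_probability(reach.intercept_event, lp_e)
    p20_f = reach_20_month_probability(reach.intercept_fatal, lp_f)
    p12_e = convert_period_probability(p20_e, reach.horizon_months, 12.0)
    p12_f = convert_period_probability(p20_f, reach.horizon_months, 12.0)
    return np.asarray(p12_e), np.asarray(p12_f)


# ---------------------------------------------------------------------------
# Substates

CHD_SUBSTATES = ("stable_angina", "unstable_angina", "mi", "surgery", "unclassified_chd")
CVA_SUBSTATES = ("tia", "haemorrhagic_stroke", "ischaemic_stroke", "unspecified_cva")
SECONDARY_SUBSTATES = ("secondary_mi", "secondary_stroke")


@dataclass(frozen=True)
class SubstateTable:
    """Severity allocation for realized events.

    ``chd`` / ``cva``: non-fatal substate proportions within each primary
    event class; ``fatal_chd`` / ``fatal_cva``: fraction of primary events
    of that class that are immediately fatal; ``secondary_nonfatal``:
    MI/stroke split of non-fatal secondary events; fatal secondary events
    are split equally between MI and stroke by assumption.
    """

    chd: dict[str, float]
    cva: dict[str, float]
    fatal_chd: float
    fatal_cva: float
    secondary_nonfatal: dict[str, float]
    secondary_fatal: dict[str, float] = field(
        default_factory=lambda: {"secondary_mi": 0.5, "secondary_stroke": 0.5})

    def __post_init__(self):
        for label, block, levels in (
            ("chd", self.chd, CHD_SUBSTATES),
            ("cva", self.cva, CVA_SUBSTATES),
            ("secondary_nonfatal", self.secondary_nonfatal, SECONDARY_SUBSTATES),
            ("secondary_fatal", self.secondary_fatal, SECONDARY_SUBSTATES),
        ):
            if set(block) != set(levels):
                raise TransitionConfigError(f"{label}: substates must be {levels}")
            vals = list(block.values())
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise TransitionConfigError(f"{label}: proportions must be in [0,1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise TransitionConfigError(f"{label}: proportions sum to {sum(vals)!r}, not 1")
        for label, frac in (("fatal_chd", self.fatal_chd), ("fatal_cva", self.fatal_cva)):
            if not 0.0 <= frac <= 1.0:
                raise TransitionConfigError(f"{label} must be in [0,1], got {frac}")

    def probs(self, event_class: str) -> tuple[tuple[str, ...], np.ndarray]:
        block = {"chd": self.chd, "cva": self.cva,
                 "secondary_nonfatal": self.secondary_nonfatal,
                 "secondary_fatal": self.secondary_fatal}[event_class]
        levels = tuple(block)
        return levels, np.asarray([block[k] for k in levels], dtype=float)

    def to_dict(self) -> dict:
        return {"chd": dict(self.chd), "cva": dict(self.cva),
                "fatal_chd": self.fatal_chd, "fatal_cva": self.fatal_cva,
                "secondary_nonfatal": dict(self.secondary_nonfatal),
                "secondary_fatal": dict(self.secondary_fatal)}

    @classmethod
    def from_dict(cls, d: dict) -> "SubstateTable":
        kwargs = dict(chd=d["chd"], cva=d["cva"], fatal_chd=float(d["fatal_chd"]),
                      fatal_cva=float(d["fatal_cva"]),
                      secondary_nonfatal=d["secondary_nonfatal"])
        if "secondary_fatal" in d:
            kwargs["secondary_fatal"] = d["secondary_fatal"]
        return cls(**kwargs)


def allocate_substate(event_class: str, table: SubstateTable, rng: np.random.Generator,
                      u: float | None = None) -> str:
    """Draw the substate label for a realized event of ``event_class``
    ('chd', 'cva', 'secondary_nonfatal' or 'secondary_fatal').  Uses the
    inverse-CDF of the substate proportions; ``u`` overrides the uniform
    draw (used by the engine's pre-drawn streams)."""
    levels, probs = table.probs(event_class)
    if u is None:
        u = rng.random()
    idx = int(np.searchsorted(np.cumsum(probs), u, side="right"))
    return levels[min(idx, len(levels) - 1)]


# ---------------------------------------------------------------------------
# Packaged synthetic defaults

def load_weibull_model(path) -> WeibullSurvivalModel:
    with open(path) as fh:
        return WeibullSurvivalModel.from_dict(json.load(fh))


def load_reach_model(path) -> ReachModel:
    with open(path) as fh:
        return ReachModel.from_dict(json.load(fh))


def default_transition_models() -> dict:
    """Synthetic default transition models shipped with the package:
    primary CHD / CVA Weibulls, other-cause death Weibull, secondary-event
    equations and the substate table."""
    data = resources.files("primrose_sim.data")
    out = {
        "chd": WeibullSurvivalModel.from_dict(
            json.loads((data / "synthetic_weibull_chd.json").read_text())),
        "cva": WeibullSurvivalModel.from_dict(
            json.loads((data / "synthetic_weibull_cva.json").read_text())),
        "death_other": WeibullSurvivalModel.from_dict(
            json.loads((data / "synthetic_weibull_death_other.json").read_text())),
        "reach": ReachModel.from_dict(
            json.loads((data / "synthetic_reach_secondary.json").read_text())),
        "substates": SubstateTable.from_dict(
            json.loads((data / "synthetic_substate_table.json").read_text())),
    }
    return out
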