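"""Ten-year CVD risk algorithms and threshold classification.

A :class:`RiskAlgorithm` is a named linear-predictor coefficient set with a
baseline survival at 10 years, in one of two equivalent forms:

* a proportional-hazards baseline ``S0(10)``, giving
  ``risk = 1 − S0(10)^exp(LP)``; or
* Weibull parameters (log-scale intercept alpha, shape gamma), giving
  ``risk = 1 − exp(−exp(alpha + LP) · 10^gamma)`` — the 10-year special case
  of the survival models used for annual transitions.

Four synthetic default algorithms ship with the package (general-population
lipid and BMI variants, SMI-specific lipid and BMI variants).  Their
coefficients are NOT the published ones (those live in an unavailable
supplement); they are constructed so that relative behaviour matches the
published pattern — the SMI-specific BMI algorithm classifies the most
patients as high risk and the general BMI algorithm the fewest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .features import linear_predictor_frame

__all__ = [
    "RiskAlgorithm",
    "ThresholdPolicy",
    "linear_predictor",
    "ten_year_risk",
    "classify",
    "score_cohort",
    "load_algorithm",
    "default_algorithms",
    "ARM_NAMES",
]

ARM_NAMES = ("general_lipid", "smi_lipid", "general_bmi", "smi_bmi", "none")


class RiskConfigError(ValueError):
    """Invalid risk-algorithm configuration."""


@dataclass(frozen=True)
class ThresholdPolicy:
    """High-risk classification threshold on the 10-year risk scale.

    Classification is strict: a patient is high risk iff risk > threshold
    (a score exactly at the threshold is low risk)."""

    threshold: float = 0.10

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise RiskConfigError(f"threshold must be in (0,1), got {self.threshold}")


@dataclass(frozen=True)
class RiskAlgorithm:
    """Named 10-year CVD risk score: LP coefficients + baseline survival."""

    name: str
    variant: str                       # "lipid" or "bmi"
    requires_blood_test: bool
    coefficients: dict[str, float]
    centering: dict[str, float] = field(default_factory=dict)
    s0_10: float | None = None         # proportional-hazards baseline S0(10)
    alpha: float | None = None         # Weibull log-scale intercept
    gamma: float | None = None         # Weibull shape

    def __post_init__(self):
        if self.variant not in ("lipid", "bmi"):
            raise RiskConfigError(f"{self.name}: variant must be lipid|bmi, got {self.variant!r}")
        has_s0 = self.s0_10 is not None
        has_weibull = self.alpha is not None and self.gamma is not None
        if has_s0 == has_weibull:
            raise RiskConfigError(f"{self.name}: provide exactly one of s0_10 or (alpha, gamma)")
        if has_s0 and not 0.0 < self.s0_10 <= 1.0:
            raise RiskConfigError(f"{self.name}: S0(10) must be in (0,1], got {self.s0_10}")
        if has_weibull and self.gamma <= 0:
            raise RiskConfigError(f"{self.name}: Weibull shape must be > 0, got {self.gamma}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        baseline = {"s0_10": self.s0_10} if self.s0_10 is not None else {
            "alpha": self.alpha, "gamma": self.gamma}
        return {
            "name": self.name,
            "variant": self.variant,
            "requires_blood_test": self.requires_blood_test,
            "centering": dict(self.centering),
            "coefficients": dict(self.coefficients),
            "baseline": baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskAlgorithm":
        baseline = d.get("baseline", {})
        return cls(
            name=d["name"],
            variant=d["variant"],
            requires_blood_test=bool(d["requires_blood_test"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            centering={k: float(v) for k, v in d.get("centering", {}).items()},
            s0_10=baseline.get("s0_10"),
            alpha=baseline.get("alpha"),
            gamma=baseline.get("gamma"),
        )


def linear_predictor(patient, alg: RiskAlgorithm) -> float:
    """LP = Σ β_i (x_i − c_i) for one patient (mapping or single-row frame)."""
    frame = _as_frame(patient)
    return float(linear_predictor_frame(frame, alg.coefficients, alg.centering, alg.name)[0])


def _as_frame(patient) -> pd.DataFrame:
    if isinstance(patient, pd.DataFrame):
        return patient
    if isinstance(patient, pd.Series):
        return patient.to_frame().T
    return pd.DataFrame([dict(patient)])


def ten_year_risk(lp, alg: RiskAlgorithm):
    """10-year CVD event probability for linear predictor(s) ``lp``.

    Strictly increasing in LP; in [0, 1].  Scalar in, scalar out.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError(f"{alg.name}: non-finite linear predictor")
    if alg.s0_10 is not None:
        risk = 1.0 - alg.s0_10 ** np.exp(lp)
    else:
        risk = 1.0 - np.exp(-np.exp(alg.alpha + lp) * 10.0 ** alg.gamma)
    return float(risk) if risk.ndim == 0 else risk


def classify(risk, policy: ThresholdPolicy):
    """'high' iff risk strictly exceeds the threshold, else 'low'."""
    r = np.asarray(risk, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risk must be in [0,1]")
    out = np.where(r > policy.threshold, "high", "low")
    return str(out) if out.ndim == 0 else out


def score_cohort(cohort: pd.DataFrame, alg: RiskAlgorithm,
                 policy: ThresholdPolicy | None = None) -> pd.DataFrame:
    """Risk scores (and classification, if a policy is given) for a cohort."""
    lp = linear_predictor_frame(cohort, alg.coefficients, alg.centering, alg.name)
    out = pd.DataFrame({"id": cohort["id"].to_numpy(), "lp": lp,
                        "risk": ten_year_risk(lp, alg)})
    if policy is not None:
        out["risk_class"] = classify(out["risk"].to_numpy(), policy)
    return out


def load_algorithm(path) -> RiskAlgorithm:
    with open(path) as fh:
        return RiskAlgorithm.from_dict(json.load(fh))


def default_algorithms() -> dict[str, RiskAlgorithm]:
    """The four synthetic default algorithms shipped with the package,
    keyed by arm name (general_lipid, smi_lipid, general_bmi, smi_bmi)."""
    out = {}
    for arm in ARM_NAMES[:4]:
        ref = resources.files("primrose_sim.data") / f"synthetic_{arm}_algorithm.json"
        out[arm] = RiskAlgorithm.from_dict(json.loads(ref.read_text()))
    return out
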