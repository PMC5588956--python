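"""Baseline treatment assignment (the decision-tree stage).

At model entry every patient is mapped to exactly one treatment status:

* ``new_statin`` — classified high risk and not already on statins; receives
  a new prescription (annual cost) and the statin relative-risk reduction.
* ``continue_statin`` — already on statins at baseline with cholesterol at
  target; continues unchanged.  Their primary-event risk is already
  conditioned on statin use through the baseline-statin covariate of the
  survival models, so no further risk reduction is applied.
* ``statin_altered`` — already on statins but cholesterol above target
  (total > 5 mmol/L or total/HDL ratio > 4); prescription intensified at a
  configured average cost delta.  No additional risk reduction, as for
  continuers.
* ``usual_care`` — low risk, not on statins; no treatment cost.

The cholesterol target test uses baseline values once, at entry; nothing is
re-checked in later cycles.  In the no-algorithm arm there is no risk
classification, so only the baseline-statin branches apply and nobody can
be newly prescribed statins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TreatmentPlan", "assign_treatment", "assign_treatment_frame"]

STATUSES = ("new_statin", "continue_statin", "statin_altered", "usual_care")


@dataclass(frozen=True)
class TreatmentPlan:
    """One patient's treatment status for the full model horizon."""

    status: str
    annual_statin_cost: float
    rr_applies: bool

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown treatment status {self.status!r}")
        if self.annual_statin_cost < 0:
            raise ValueError("annual statin cost must be >= 0")
        if self.rr_applies != (self.status == "new_statin"):
            raise ValueError("the statin RR applies exactly to new prescriptions")
        if self.status == "usual_care" and self.annual_statin_cost != 0:
            raise ValueError("usual care carries no treatment cost")


def _above_cholesterol_target(total_chol: float, hdl_chol: float) -> bool:
    return total_chol > 5.0 or (total_chol / hdl_chol) > 4.0


def assign_treatment(patient, risk_class: str | None, cost_schedule) -> TreatmentPlan:
    """Decision tree for one patient.

    ``risk_class`` is 'high' or 'low' from the risk algorithm, or None for
    the no-algorithm arm.  ``cost_schedule`` supplies ``statin_annual`` and
    ``statin_alteration_annual``.
    """
    if risk_class not in ("high", "low", None):
        raise ValueError(f"risk_class must be high|low|None, got {risk_class!r}")
    p = patient if isinstance(patient, dict) else dict(patient)
    on_statin = bool(p["on_statin_baseline"])
    if on_statin:
        if _above_cholesterol_target(float(p["total_chol"]), float(p["hdl_chol"])):
            return TreatmentPlan("statin_altered", cost_schedule.statin_alteration_annual, False)
        return TreatmentPlan("continue_statin", 0.0, False)
    if risk_class == "high":
        return TreatmentPlan("new_statin", cost_schedule.statin_annual, True)
    return TreatmentPlan("usual_care", 0.0, False)


def assign_treatment_frame(cohort: pd.DataFrame, risk_class: np.ndarray | None,
                           cost_schedule) -> pd.DataFrame:
    """Vectorized decision tree over a cohort.

    Returns a DataFrame (id, status, annual_statin_cost, rr_applies) with
    exactly one status per patient.
    """
    n = len(cohort)
    on_statin = cohort["on_statin_baseline"].to_numpy().astype(bool)
    total = cohort["total_chol"].to_numpy(float)
    hdl = cohort["hdl_chol"].to_numpy(float)
    above_target = (total > 5.0) | (total / hdl > 4.0)
    high = np.zeros(n, dtype=bool) if risk_class is None else (np.asarray(risk_class) == "high")

    status = np.full(n, "usual_care", dtype=object)
    status[on_statin & above_target] = "statin_altered"
    status[on_statin & ~above_target] = "continue_statin"
    status[~on_statin & high] = "new_statin"

    cost = np.zeros(n)
    cost[status == "new_statin"] = cost_schedule.statin_annual
    cost[status == "statin_altered"] = cost_schedule.statin_alteration_annual
    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "status": status,
        "annual_statin_cost": cost,
        "rr_applies": status == "new_statin",
    })
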