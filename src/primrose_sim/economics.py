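"""Cost and QALY accrual, discounting, incremental analysis, NMB and CEACs.

Costs fall into three buckets mirroring the published results layout:
administering the risk algorithm (once, at entry), new/altered statin
prescriptions (annual while alive), and CVD events (an acute-year cost at
the event plus a maintenance cost every subsequent alive year; fatal events
carry a one-off cost).  Utilities start from the stable-SMI baseline
(0.865) and non-fatal events subtract persistent additive decrements,
floored at zero; dead cycles contribute nothing.

Discounting is annuity-due at 3.5%/year: all events occur at the start of
a cycle, so cycle-1 flows are undiscounted and cycle-t flows are divided
by 1.035^(t−1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .engine import (DEAD_CVD, EVENT_CODE, EVENT_LABELS, ArmSimulation,
                     PatientTrajectory)
from .transitions import CHD_SUBSTATES, CVA_SUBSTATES

__all__ = [
    "CostSchedule", "UtilitySchedule", "EconomicResult",
    "discount", "discount_factor", "accrue", "accrue_arm", "aggregate",
    "incremental", "net_monetary_benefit", "ceac", "default_economics",
]

DEFAULT_DISCOUNT_RATE = 0.035

NONFATAL_SUBSTATES = CHD_SUBSTATES + CVA_SUBSTATES + ("secondary_mi", "secondary_stroke")


class EconomicsConfigError(ValueError):
    """Missing or invalid cost/utility configuration."""


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs in GBP (2012/13 prices assumed by convention).

    ``event_costs`` maps every non-fatal substate to
    {"acute": first-year cost, "subsequent": each later alive year} and the
    fatal classes ("fatal_chd", "fatal_cva") to {"acute": one-off cost}.
    """

    algorithm_cost_blood: float = 20.0
    algorithm_cost_no_blood: float = 19.0
    statin_annual: float = 21.0
    statin_alteration_annual: float = 10.0
    event_costs: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("algorithm_cost_blood", "algorithm_cost_no_blood",
                     "statin_annual", "statin_alteration_annual"):
            if getattr(self, name) < 0:
                raise EconomicsConfigError(f"{name} must be >= 0")
        for sub in NONFATAL_SUBSTATES:
            entry = self.event_costs.get(sub)
            if entry is None or "acute" not in entry or "subsequent" not in entry:
                raise EconomicsConfigError(f"event cost missing for substate {sub!r}")
        for sub in ("fatal_chd", "fatal_cva"):
            if sub not in self.event_costs or "acute" not in self.event_costs[sub]:
                raise EconomicsConfigError(f"event cost missing for {sub!r}")
        for sub, entry in self.event_costs.items():
            if any(v < 0 for v in entry.values()):
                raise EconomicsConfigError(f"negative event cost for {sub!r}")

    def to_dict(self) -> dict:
        return {"algorithm_cost_blood": self.algorithm_cost_blood,
                "algorithm_cost_no_blood": self.algorithm_cost_no_blood,
                "statin_annual": self.statin_annual,
                "statin_alteration_annual": self.statin_alteration_annual,
                "event_costs": {k: dict(v) for k, v in self.event_costs.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "CostSchedule":
        return cls(algorithm_cost_blood=float(d["algorithm_cost_blood"]),
                   algorithm_cost_no_blood=float(d["algorithm_cost_no_blood"]),
                   statin_annual=float(d["statin_annual"]),
                   statin_alteration_annual=float(d["statin_alteration_annual"]),
                   event_costs={k: {kk: float(vv) for kk, vv in v.items()}
                                for k, v in d["event_costs"].items()})


@dataclass(frozen=True)
class UtilitySchedule:
    """Health-state utilities.

    ``base_utility`` is the utility of stable, managed SMI (0.865);
    ``decrements`` maps each non-fatal substate to a persistent utility
    decrement.  ``alt_utilities`` carries the sensitivity-analysis baselines
    (SMI relapse 0.479, extrapyramidal symptoms 0.604).  Composite
    decrements (surgery = MI; unclassified CHD = weighted mean of the CHD
    substates; unspecified CVA = weighted mean of stroke and TIA) are
    computed by :func:`composite_decrements` from a partial table.
    """

    base_utility: float = 0.865
    decrements: dict[str, float] = field(default_factory=dict)
    alt_utilities: dict[str, float] = field(
        default_factory=lambda: {"relapse": 0.479, "eps": 0.604})

    def __post_init__(self):
        if not 0.0 <= self.base_utility <= 1.0:
            raise EconomicsConfigError("base utility must be in [0,1]")
        for sub in NONFATAL_SUBSTATES:
            if sub not in self.decrements:
                raise EconomicsConfigError(f"utility decrement missing for substate {sub!r}")
            if self.decrements[sub] < 0:
                raise EconomicsConfigError(f"negative decrement for {sub!r}")

    def to_dict(self) -> dict:
        return {"base_utility": self.base_utility, "decrements": dict(self.decrements),
                "alt_utilities": dict(self.alt_utilities)}

    @classmethod
    def from_dict(cls, d: dict) -> "UtilitySchedule":
        return cls(base_utility=float(d["base_utility"]),
                   decrements={k: float(v) for k, v in d["decrements"].items()},
                   alt_utilities={k: float(v) for k, v in d.get("alt_utilities", {}).items()})


def composite_decrements(partial: dict[str, float], chd_weights: dict[str, float],
                         cva_weights: dict[str, float],
                         secondary_weights: dict[str, float] | None = None) -> dict[str, float]:
    """Fill composite substates from a partial decrement table.

    surgery gets the MI decrement; unclassified CHD the substate-weighted
    mean of stable/unstable angina and MI; unspecified CVA the weighted
    mean of stroke and TIA; secondary MI/stroke reuse the primary MI and
    ischaemic-stroke decrements unless given explicitly.
    """
    d = dict(partial)
    d.setdefault("surgery", d["mi"])
    named = ("stable_angina", "unstable_angina", "mi")
    w = np.array([chd_weights[k] for k in named])
    d.setdefault("unclassified_chd", float(np.average([d[k] for k in named], weights=w)))
    stroke_like = ("haemorrhagic_stroke", "ischaemic_stroke", "tia")
    w = np.array([cva_weights[k] for k in stroke_like])
    d.setdefault("unspecified_cva", float(np.average([d[k] for k in stroke_like], weights=w)))
    d.setdefault("secondary_mi", d["mi"])
    d.setdefault("secondary_stroke", d["ischaemic_stroke"])
    return d


# ---------------------------------------------------------------------------
# Discounting

def discount_factor(t: int, rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Annuity-due discount factor for cycle t: 1/(1+rate)^(t−1)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if t < 1:
        raise ValueError("cycle must be >= 1")
    return (1.0 + rate) ** -(t - 1)


def discount(amount: float, t: int, rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Present value of an amount occurring at the start of cycle t."""
    return amount * discount_factor(t, rate)


# ---------------------------------------------------------------------------
# Accrual

_FATAL_COST_KEY = {
    EVENT_CODE["fatal_primary_chd"]: "fatal_chd",
    EVENT_CODE["fatal_primary_cva"]: "fatal_cva",
    EVENT_CODE["secondary_fatal_mi"]: "fatal_chd",
    EVENT_CODE["secondary_fatal_stroke"]: "fatal_cva",
}


def accrue(trajectory: PatientTrajectory, costs: CostSchedule, utils: UtilitySchedule,
           algorithm_applied: bool, requires_blood: bool,
           rate: float = DEFAULT_DISCOUNT_RATE) -> pd.DataFrame:
    """Per-cycle cost and QALY streams for one patient.

    Reference (scalar) implementation of the accrual rules; the engine-level
    :func:`accrue_arm` is the vectorized equivalent.  Returns one row per
    simulated cycle with undiscounted and discounted columns.
    """
    rows = []
    active_decrement = 0.0
    subsequent_cost = 0.0
    plan_cost = float(trajectory.plan.annual_statin_cost)
    for oc in trajectory.outcomes:
        t = oc.cycle
        dead = oc.state in ("dead_cvd", "dead_other")
        alg_cost = 0.0
        if t == 1 and algorithm_applied:
            alg_cost = costs.algorithm_cost_blood if requires_blood else costs.algorithm_cost_no_blood
        statin_cost = 0.0 if dead else plan_cost
        event_cost = subsequent_cost if not dead else 0.0
        ev = oc.event
        if ev and ev != "death_other":
            code = EVENT_CODE[ev]
            if code in _FATAL_COST_KEY:
                event_cost += costs.event_costs[_FATAL_COST_KEY[code]]["acute"]
            else:
                entry = costs.event_costs.get(ev)
                if entry is None:
                    raise EconomicsConfigError(f"substate {ev!r} lacks a cost entry")
                event_cost += entry["acute"]
                subsequent_cost += entry["subsequent"]
                if ev not in utils.decrements:
                    raise EconomicsConfigError(f"substate {ev!r} lacks a utility decrement")
                active_decrement += utils.decrements[ev]
        qaly = 0.0 if dead else max(utils.base_utility - active_decrement, 0.0)
        dfac = discount_factor(t, rate)
        total = alg_cost + statin_cost + event_cost
        rows.append((t, alg_cost, statin_cost, event_cost, total, total * dfac,
                     qaly, qaly * dfac))
    return pd.DataFrame(rows, columns=[
        "cycle", "algorithm_cost", "statin_cost", "event_cost",
        "cost", "cost_discounted", "qaly", "qaly_discounted"])


def accrue_arm(sim: ArmSimulation, costs: CostSchedule, utils: UtilitySchedule,
               rate: float = DEFAULT_DISCOUNT_RATE) -> dict[str, np.ndarray]:
    """Vectorized accrual over a simulated arm.

    Returns per-patient totals: algorithm/statin/event cost and QALYs, each
    undiscounted and discounted.
    """
    n, T = sim.events.shape
    acute = np.zeros(len(EVENT_LABELS))
    subsequent = np.zeros(len(EVENT_LABELS))
    decrement = np.zeros(len(EVENT_LABELS))
    for code, label in enumerate(EVENT_LABELS):
        if not label or label == "death_other":
            continue
        if code in _FATAL_COST_KEY:
            acute[code] = costs.event_costs[_FATAL_COST_KEY[code]]["acute"]
        else:
            acute[code] = costs.event_costs[label]["acute"]
            subsequent[code] = costs.event_costs[label]["subsequent"]
            decrement[code] = utils.decrements[label]

    plan_cost = sim.plans["annual_statin_cost"].to_numpy(float)
    alg_unit = (costs.algorithm_cost_blood if sim.requires_blood_test
                else costs.algorithm_cost_no_blood) if sim.algorithm_applied else 0.0

    zeros = np.zeros(n)
    out = {k: zeros.copy() for k in
           ("algorithm_cost", "statin_cost", "event_cost", "qaly",
            "algorithm_cost_disc", "statin_cost_disc", "event_cost_disc", "qaly_disc")}
    active_decrement = np.zeros(n)
    running_subsequent = np.zeros(n)
    prev_dead = np.zeros(n, dtype=bool)

    for t in range(1, T + 1):
        dfac = discount_factor(t, rate)
        ev = sim.events[:, t - 1]
        dead = sim.states[:, t - 1] >= DEAD_CVD
        alive_cycle = ~dead

        alg_cost = np.full(n, alg_unit) if t == 1 else zeros
        statin_cost = np.where(alive_cycle, plan_cost, 0.0)
        event_cost = np.where(alive_cycle & ~prev_dead, running_subsequent, 0.0)
        event_cost = event_cost + acute[ev]
        active_decrement += decrement[ev]
        running_subsequent += subsequent[ev]
        qaly = np.where(alive_cycle,
                        np.maximum(utils.base_utility - active_decrement, 0.0), 0.0)

        out["algorithm_cost"] += alg_cost
        out["statin_cost"] += statin_cost
        out["event_cost"] += event_cost
        out["qaly"] += qaly
        out["algorithm_cost_disc"] += alg_cost * dfac
        out["statin_cost_disc"] += statin_cost * dfac
        out["event_cost_disc"] += event_cost * dfac
        out["qaly_disc"] += qaly * dfac
        prev_dead = dead
    return out


@dataclass(frozen=True)
class EconomicResult:
    """Arm-level totals (per cohort, typically 1000 patients, over 10 years)."""

    arm: str
    n_patients: int
    horizon: int
    cost_algorithm: float
    cost_statins: float
    cost_events: float
    cost_total: float
    cost_algorithm_disc: float
    cost_statins_disc: float
    cost_events_disc: float
    cost_total_disc: float
    qalys: float
    qalys_disc: float
    event_tally: dict[str, int]

    def as_row(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "arm", "n_patients", "horizon", "cost_algorithm", "cost_statins",
            "cost_events", "cost_total", "cost_algorithm_disc", "cost_statins_disc",
            "cost_events_disc", "cost_total_disc", "qalys", "qalys_disc")}
        d.update({f"events_{k}": v for k, v in sorted(self.event_tally.items())})
        return d


def aggregate(sim: ArmSimulation, costs: CostSchedule, utils: UtilitySchedule,
              rate: float = DEFAULT_DISCOUNT_RATE) -> EconomicResult:
    """Sum per-patient accruals into an arm-level :class:`EconomicResult`."""
    if sim.n_patients == 0:
        raise ValueError("cannot aggregate an empty arm")
    acc = accrue_arm(sim, costs, utils, rate)
    s = {k: float(v.sum()) for k, v in acc.items()}
    return EconomicResult(
        arm=sim.arm, n_patients=sim.n_patients, horizon=sim.horizon,
        cost_algorithm=s["algorithm_cost"], cost_statins=s["statin_cost"],
        cost_events=s["event_cost"],
        cost_total=s["algorithm_cost"] + s["statin_cost"] + s["event_cost"],
        cost_algorithm_disc=s["algorithm_cost_disc"],
        cost_statins_disc=s["statin_cost_disc"],
        cost_events_disc=s["event_cost_disc"],
        cost_total_disc=s["algorithm_cost_disc"] + s["statin_cost_disc"] + s["event_cost_disc"],
        qalys=s["qaly"], qalys_disc=s["qaly_disc"],
        event_tally=sim.event_tally(),
    )


def incremental(result: EconomicResult, reference: EconomicResult) -> tuple[float, float]:
    """Discounted (Δcost, ΔQALY) of result minus reference."""
    if result.n_patients != reference.n_patients or result.horizon != reference.horizon:
        raise ValueError("incremental comparison requires matching n and horizon")
    return (result.cost_total_disc - reference.cost_total_disc,
            result.qalys_disc - reference.qalys_disc)


def net_monetary_benefit(qalys: float, costs: float, wtp: float) -> float:
    """NMB = willingness-to-pay × QALYs − costs (all discounted)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * qalys - costs


def ceac(psa_results: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA draws.

    ``psa_results`` has one row per (draw, arm) with columns
    (draw, arm, cost, qaly).  For each willingness-to-pay value, returns the
    probability each arm has the highest NMB across draws (ties split
    equally).  Probabilities sum to 1 at every WTP.
    """
    if len(psa_results) == 0:
        raise ValueError("CEAC requires at least one PSA draw")
    arms = sorted(psa_results["arm"].unique())
    if len(arms) < 2:
        raise ValueError("CEAC requires at least two arms")
    wide_cost = psa_results.pivot(index="draw", columns="arm", values="cost")[arms]
    wide_qaly = psa_results.pivot(index="draw", columns="arm", values="qaly")[arms]
    if wide_cost.isna().any().any():
        raise ValueError("every draw must include every arm")
    n_draws = len(wide_cost)
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * wide_qaly.to_numpy() - wide_cost.to_numpy()
        best = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = is_best / is_best.sum(axis=1, keepdims=True)
        probs = share.sum(axis=0) / n_draws
        for arm, p in zip(arms, probs):
            rows.append((float(wtp), arm, float(p)))
    return pd.DataFrame(rows, columns=["wtp", "arm", "probability"])


def default_economics() -> tuple[CostSchedule, UtilitySchedule]:
    """The synthetic default cost and utility schedules shipped in data/."""
    ref = resources.files("primrose_sim.data") / "synthetic_economics.yaml"
    d = yaml.safe_load(ref.read_text())
    return CostSchedule.from_dict(d["costs"]), UtilitySchedule.from_dict(d["utilities"])
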