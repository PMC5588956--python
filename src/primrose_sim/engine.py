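"""Patient-level simulation engine for the 10-cycle state-transition model.

Each patient runs through annual cycles of the health-state machine
(healthy → post-primary-event → dead), with events realized by comparing
patient-specific probabilities against pre-drawn uniform random numbers:
an event occurs in a cycle iff its probability exceeds the patient's
uniform draw for that (cycle, draw-slot).  All events occur at the start
of a cycle, dead states are absorbing, and a patient has at most one event
per cycle.

Within a cycle the draw order is: other-cause death, then (if healthy)
primary CHD, then primary CVA, then (if post-primary since an earlier
cycle) fatal secondary, then non-fatal secondary.  The order is a modelling
decision documented in the methods note.

Random numbers are organised as one uniform array indexed by
(patient, cycle, draw-slot), generated from a (master seed, replicate)
pair.  Because the array depends only on the seed pair and the cohort
order — never on the scenario arm — all arms see identical draws (common
random numbers), so between-arm differences are attributable to treatment
rather than Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk import ARM_NAMES, score_cohort
from .transitions import (EffectParameters, SubstateTable,
                          cycle_probability_frame,
                          secondary_annual_risks_frame)
from .treatment import assign_treatment_frame

__all__ = [
    "EVENT_LABELS", "STATE_LABELS", "CycleOutcome", "PatientTrajectory",
    "ArmSimulation", "simulate_patient", "simulate_arm",
    "trajectories_to_frame",
]

# Event codes (0 = no event).  Non-fatal primary substates 1..9, fatal
# primary 10..11, secondary 12..15, other-cause death 16.
EVENT_LABELS = (
    "", "stable_angina", "unstable_angina", "mi", "surgery", "unclassified_chd",
    "tia", "haemorrhagic_stroke", "ischaemic_stroke", "unspecified_cva",
    "fatal_primary_chd", "fatal_primary_cva",
    "secondary_mi", "secondary_stroke",
    "secondary_fatal_mi", "secondary_fatal_stroke",
    "death_other",
)
EVENT_CODE = {label: i for i, label in enumerate(EVENT_LABELS)}

STATE_LABELS = ("healthy", "post_primary", "dead_cvd", "dead_other")
HEALTHY, POST_PRIMARY, DEAD_CVD, DEAD_OTHER = range(4)

# Draw-slot layout of the uniform array (patient, cycle, slot).
SLOT_DEATH_OTHER, SLOT_CHD, SLOT_CHD_FATAL, SLOT_CHD_SUB, SLOT_CVA, \
    SLOT_CVA_FATAL, SLOT_CVA_SUB, SLOT_SEC_FATAL, SLOT_SEC, SLOT_SEC_SUB = range(10)
N_SLOTS = 10

HORIZON = 10


@dataclass(frozen=True)
class CycleOutcome:
    cycle: int
    state: str
    event: str | None
    on_statin: bool


@dataclass
class PatientTrajectory:
    """One patient's ordered cycle outcomes; stops at death."""

    patient_id: int
    plan: object
    outcomes: list[CycleOutcome]
    terminated_at: int | None = None

    def __len__(self) -> int:
        return len(self.outcomes)


def _substate_from_u(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Vectorized inverse-CDF categorical draw (index into probs)."""
    cum = np.cumsum(probs)
    idx = np.searchsorted(cum, u, side="right")
    return np.minimum(idx, len(probs) - 1)


def _simulate_core(p_death: np.ndarray, p_chd: np.ndarray, p_cva: np.ndarray,
                   p_sec_nonfatal: np.ndarray, p_sec_fatal: np.ndarray,
                   substates: SubstateTable, uniforms: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Run the state machine for a cohort.

    All probability inputs are per-patient (p_death/p_chd/p_cva per cycle,
    secondary constant); ``uniforms`` has shape (n, T, N_SLOTS).  Returns
    (events, states), each (n, T); states give the state at the *end* of
    each cycle, carried forward after death.
    """
    n, T, _ = uniforms.shape
    events = np.zeros((n, T), dtype=np.int8)
    states = np.zeros((n, T), dtype=np.int8)
    state = np.zeros(n, dtype=np.int8)

    chd_levels, chd_probs = substates.probs("chd")
    cva_levels, cva_probs = substates.probs("cva")
    _, sec_nf_probs = substates.probs("secondary_nonfatal")
    _, sec_f_probs = substates.probs("secondary_fatal")
    chd_codes = np.array([EVENT_CODE[s] for s in chd_levels])
    cva_codes = np.array([EVENT_CODE[s] for s in cva_levels])
    sec_nf_codes = np.array([EVENT_CODE["secondary_mi"], EVENT_CODE["secondary_stroke"]])
    sec_f_codes = np.array([EVENT_CODE["secondary_fatal_mi"], EVENT_CODE["secondary_fatal_stroke"]])

    for t in range(T):
        u = uniforms[:, t, :]
        alive = state < DEAD_CVD
        ev = np.zeros(n, dtype=np.int8)

        # 1. other-cause death
        dies_other = alive & (p_death[:, t] > u[:, SLOT_DEATH_OTHER])
        ev[dies_other] = EVENT_CODE["death_other"]
        new_state = state.copy()
        new_state[dies_other] = DEAD_OTHER

        # 2. primary events for the still-healthy
        healthy = alive & ~dies_other & (state == HEALTHY)
        chd_event = healthy & (p_chd[:, t] > u[:, SLOT_CHD])
        chd_fatal = chd_event & (substates.fatal_chd > u[:, SLOT_CHD_FATAL])
        chd_nonfatal = chd_event & ~chd_fatal
        ev[chd_fatal] = EVENT_CODE["fatal_primary_chd"]
        new_state[chd_fatal] = DEAD_CVD
        if chd_nonfatal.any():
            idx = _substate_from_u(u[chd_nonfatal, SLOT_CHD_SUB], chd_probs)
            ev[chd_nonfatal] = chd_codes[idx]
            new_state[chd_nonfatal] = POST_PRIMARY

        cva_candidate = healthy & ~chd_event
        cva_event = cva_candidate & (p_cva[:, t] > u[:, SLOT_CVA])
        cva_fatal = cva_event & (substates.fatal_cva > u[:, SLOT_CVA_FATAL])
        cva_nonfatal = cva_event & ~cva_fatal
        ev[cva_fatal] = EVENT_CODE["fatal_primary_cva"]
        new_state[cva_fatal] = DEAD_CVD
        if cva_nonfatal.any():
            idx = _substate_from_u(u[cva_nonfatal, SLOT_CVA_SUB], cva_probs)
            ev[cva_nonfatal] = cva_codes[idx]
            new_state[cva_nonfatal] = POST_PRIMARY

        # 3. secondary events: only for patients post-primary since an
        #    earlier cycle (state entering this cycle is POST_PRIMARY)
        post = alive & ~dies_other & (state == POST_PRIMARY)
        sec_fatal = post & (p_sec_fatal > u[:, SLOT_SEC_FATAL])
        sec_nonfatal = post & ~sec_fatal & (p_sec_nonfatal > u[:, SLOT_SEC])
        if sec_fatal.any():
            idx = _substate_from_u(u[sec_fatal, SLOT_SEC_SUB], sec_f_probs)
            ev[sec_fatal] = sec_f_codes[idx]
            new_state[sec_fatal] = DEAD_CVD
        if sec_nonfatal.any():
            idx = _substate_from_u(u[sec_nonfatal, SLOT_SEC_SUB], sec_nf_probs)
            ev[sec_nonfatal] = sec_nf_codes[idx]
            # remains POST_PRIMARY

        events[:, t] = ev
        states[:, t] = new_state
        state = new_state

    return events, states


@dataclass
class ArmSimulation:
    """Result of running one scenario arm over a cohort.

    ``events[i, t]`` / ``states[i, t]`` give patient i's event and
    end-of-cycle state in cycle t+1; dead states are carried forward.
    """

    arm: str
    cohort: pd.DataFrame
    plans: pd.DataFrame
    events: np.ndarray
    states: np.ndarray
    algorithm_applied: bool
    requires_blood_test: bool
    seed: int
    replicate: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.cohort)

    @property
    def horizon(self) -> int:
        return self.events.shape[1]

    def death_cycle(self) -> np.ndarray:
        """Cycle of death per patient (0 if alive through the horizon)."""
        dead = self.states >= DEAD_CVD
        first = np.argmax(dead, axis=1) + 1
        first[~dead.any(axis=1)] = 0
        return first

    def event_tally(self) -> dict[str, int]:
        """Counts of each realized event type over all patients and cycles."""
        counts = np.bincount(self.events.ravel(), minlength=len(EVENT_LABELS))
        return {EVENT_LABELS[i]: int(c) for i, c in enumerate(counts) if i > 0}

    def trajectories(self) -> list[PatientTrajectory]:
        """Materialize per-patient trajectory objects (stop at death)."""
        out = []
        plans = list(self.plans.itertuples(index=False))
        for i in range(self.n_patients):
            on_statin = plans[i].status in ("new_statin", "continue_statin", "statin_altered")
            outcomes = []
            terminated = None
            for t in range(self.horizon):
                st = int(self.states[i, t])
                ev = int(self.events[i, t])
                outcomes.append(CycleOutcome(
                    cycle=t + 1,
                    state=STATE_LABELS[st],
                    event=EVENT_LABELS[ev] or None,
                    on_statin=on_statin and st < DEAD_CVD,
                ))
                if st >= DEAD_CVD:
                    terminated = t + 1
                    break
            out.append(PatientTrajectory(
                patient_id=int(self.cohort["id"].iloc[i]),
                plan=plans[i], outcomes=outcomes, terminated_at=terminated))
        return out


def _event_probabilities(cohort: pd.DataFrame, plans: pd.DataFrame, models: dict,
                         effects: EffectParameters, horizon: int):
    """Per-patient per-cycle probabilities for all draw classes."""
    n = len(cohort)
    p_death = np.column_stack(
        [cycle_probability_frame(models["death_other"], cohort, t) for t in range(1, horizon + 1)])
    p_chd = np.column_stack(
        [cycle_probability_frame(models["chd"], cohort, t) for t in range(1, horizon + 1)])
    p_cva = np.column_stack(
        [cycle_probability_frame(models["cva"], cohort, t) for t in range(1, horizon + 1)])
    rr_chd, rr_cva = effects.effective_rr()
    treated = plans["rr_applies"].to_numpy().astype(bool)
    p_chd[treated] *= rr_chd
    p_cva[treated] *= rr_cva
    p_sec_any, p_sec_fatal = secondary_annual_risks_frame(cohort, models["reach"])
    p_sec_nonfatal = np.maximum(p_sec_any - p_sec_fatal, 0.0)
    return p_death, p_chd, p_cva, p_sec_nonfatal, p_sec_fatal


def draw_uniforms(n: int, seed: int, replicate: int = 0, horizon: int = HORIZON) -> np.ndarray:
    """The (n, horizon, N_SLOTS) uniform array for one event-seed replicate.

    Depends only on (seed, replicate) and patient order — never on the arm —
    which is what makes common-random-number coupling across arms exact.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, replicate)))
    return rng.random((n, horizon, N_SLOTS))


def simulate_arm(cohort: pd.DataFrame, scenario: str, config, seed: int,
                 replicate: int = 0, uniforms: np.ndarray | None = None) -> ArmSimulation:
    """Score, treat and simulate a cohort under one scenario arm.

    ``scenario`` is one of the four algorithm arms or "none"; ``config`` is
    a :class:`~primrose_sim.config.RunConfig`.  The (cohort, scenario, seed,
    replicate) tuple fully determines the output.
    """
    if scenario not in ARM_NAMES:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {ARM_NAMES}")
    if scenario == "none":
        plans = assign_treatment_frame(cohort, None, config.costs)
        algorithm_applied, requires_blood = False, False
    else:
        alg = config.algorithms[scenario]
        scores = score_cohort(cohort, alg, config.threshold)
        plans = assign_treatment_frame(cohort, scores["risk_class"].to_numpy(), config.costs)
        algorithm_applied, requires_blood = True, alg.requires_blood_test
    models = config.transition_models
    probs = _event_probabilities(cohort, plans, models, config.effects, config.horizon)
    if uniforms is None:
        uniforms = draw_uniforms(len(cohort), seed, replicate, config.horizon)
    events, states = _simulate_core(*probs, models["substates"], uniforms)
    return ArmSimulation(arm=scenario, cohort=cohort, plans=plans, events=events,
                         states=states, algorithm_applied=algorithm_applied,
                         requires_blood_test=requires_blood, seed=seed, replicate=replicate)


def simulate_patient(patient, plan, models: dict, rng_stream, effects: EffectParameters | None = None,
                     horizon: int = HORIZON) -> PatientTrajectory:
    """Simulate a single patient given an assigned plan.

    ``models`` holds chd/cva/death_other Weibulls, the reach model and the
    substate table; ``rng_stream`` is a numpy Generator (or a pre-drawn
    (1, horizon, N_SLOTS) uniform array) private to this patient.
    """
    effects = effects or EffectParameters()
    frame = patient if isinstance(patient, pd.DataFrame) else pd.DataFrame([dict(patient)])
    plans = pd.DataFrame({
        "id": frame["id"].to_numpy() if "id" in frame else [0],
        "status": [plan.status],
        "annual_statin_cost": [plan.annual_statin_cost],
        "rr_applies": [plan.rr_applies],
    })
    probs = _event_probabilities(frame, plans, models, effects, horizon)
    if isinstance(rng_stream, np.ndarray):
        uniforms = rng_stream
    else:
        uniforms = rng_stream.random((1, horizon, N_SLOTS))
    events, states = _simulate_core(*probs, models["substates"], uniforms)
    sim = ArmSimulation(arm="single", cohort=frame, plans=plans, events=events,
                        states=states, algorithm_applied=False,
                        requires_blood_test=False, seed=-1)
    return sim.trajectories()[0]


def trajectories_to_frame(sim: ArmSimulation) -> pd.DataFrame:
    """Long-format (patient, cycle, state, event, on_statin) table."""
    rows = []
    for traj in sim.trajectories():
        for oc in traj.outcomes:
            rows.append((traj.patient_id, oc.cycle, oc.state, oc.event or "", oc.on_statin))
    return pd.DataFrame(rows, columns=["patient", "cycle", "state", "event", "on_statin"])
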