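"""Orchestration of the five-arm analysis and tabular reporting.

``run_all`` generates (or accepts) a cohort, runs every arm — the four
risk-algorithm arms plus no algorithm — under common random numbers,
and assembles the headline results table: cost components, QALYs,
incrementals against the no-algorithm arm, and net monetary benefit at
each willingness-to-pay value, together with a manifest sufficient to
reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone

import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .config import RunConfig
from .economics import EconomicResult, ceac, incremental, net_monetary_benefit
from .risk import ARM_NAMES
from .sensitivity import mean_arm_results

__all__ = ["RunManifest", "RunResult", "run_all", "render_table3", "render_ceac"]


@dataclass(frozen=True)
class RunManifest:
    """Provenance record: enough to reproduce any output byte-for-byte."""

    config_hash: str
    seed: int
    n_iterations: int
    n_patients: int
    arms: tuple[str, ...]
    version: str
    python: str
    timestamp: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class RunResult:
    """Five-arm results plus the derived incremental / NMB tables."""

    results: dict[str, EconomicResult]
    incrementals: pd.DataFrame        # arm, d_cost_disc, d_qalys_disc (vs none)
    nmb: pd.DataFrame                 # arm, wtp, nmb
    manifest: RunManifest
    cohort: pd.DataFrame


def run_all(config: RunConfig, seed: int | None = None, cohort: pd.DataFrame | None = None,
            n_iterations: int = 1) -> RunResult:
    """Run the complete base-case analysis.

    ``seed`` defaults to the cohort spec's seed and drives both cohort
    generation and event draws; ``n_iterations`` averages the stochastic
    patient simulation over that many event-seed replications.
    """
    seed = config.cohort_spec.seed if seed is None else seed
    if cohort is None:
        spec = dataclasses.replace(config.cohort_spec, seed=seed)
        cohort = generate_cohort(spec)
    results = mean_arm_results(cohort, config, seed, n_iterations)

    ref = results["none"]
    inc_rows, nmb_rows = [], []
    for arm in ARM_NAMES:
        d_cost, d_qaly = incremental(results[arm], ref)
        inc_rows.append((arm, d_cost, d_qaly))
        for wtp in config.wtp:
            nmb_rows.append((arm, wtp, net_monetary_benefit(
                results[arm].qalys_disc, results[arm].cost_total_disc, wtp)))

    manifest = RunManifest(
        config_hash=config.config_hash(), seed=seed, n_iterations=n_iterations,
        n_patients=len(cohort), arms=ARM_NAMES, version=__version__,
        python=platform.python_version(),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"))
    return RunResult(
        results=results,
        incrementals=pd.DataFrame(inc_rows, columns=["arm", "d_cost_disc", "d_qalys_disc"]),
        nmb=pd.DataFrame(nmb_rows, columns=["arm", "wtp", "nmb"]),
        manifest=manifest, cohort=cohort)


_TABLE_ROWS = [
    ("cost_algorithm", "Costs of administering algorithm"),
    ("cost_statins", "Costs of new statin prescriptions"),
    ("cost_events", "Costs of CVD events"),
    ("cost_total", "Total costs undiscounted"),
    ("cost_total_disc", "Total costs discounted"),
    ("qalys_disc", "QALYs discounted"),
]

_EVENT_ROWS = [
    ("stable_angina unstable_angina mi surgery unclassified_chd", "Primary non-fatal CHD"),
    ("fatal_primary_chd", "Primary fatal CHD"),
    ("tia haemorrhagic_stroke ischaemic_stroke unspecified_cva", "Primary non-fatal stroke"),
    ("fatal_primary_cva", "Primary fatal stroke"),
    ("secondary_mi secondary_stroke", "Secondary non-fatal CVD"),
    ("secondary_fatal_mi secondary_fatal_stroke", "Secondary fatal CVD"),
    ("death_other", "Death from other causes"),
]


def render_table3(run: RunResult) -> pd.DataFrame:
    """Headline results table, one row per outcome and one column per arm."""
    arms = list(ARM_NAMES)
    rows = []
    for attr, label in _TABLE_ROWS:
        rows.append([label] + [getattr(run.results[a], attr) for a in arms])
    inc = run.incrementals.set_index("arm")
    rows.append(["Cost compared with no algorithm"] + [inc.loc[a, "d_cost_disc"] for a in arms])
    rows.append(["QALYs compared with no algorithm"] + [inc.loc[a, "d_qalys_disc"] for a in arms])
    nmb = run.nmb.set_index(["arm", "wtp"])
    for wtp in sorted(run.nmb["wtp"].unique()):
        rows.append([f"NMB at £{wtp:,.0f} WTP"] + [nmb.loc[(a, wtp), "nmb"] for a in arms])
    for keys, label in _EVENT_ROWS:
        rows.append([label] + [sum(run.results[a].event_tally.get(k, 0) for k in keys.split())
                               for a in arms])
    return pd.DataFrame(rows, columns=["outcome"] + arms)


def render_ceac(curves: pd.DataFrame, path=None) -> pd.DataFrame:
    """Validate/normalize a CEAC table (wtp, arm, probability); optionally
    write it to CSV."""
    expected = {"wtp", "arm", "probability"}
    if set(curves.columns) != expected:
        raise ValueError(f"CEAC table must have columns {sorted(expected)}")
    out = curves.sort_values(["wtp", "arm"]).reset_index(drop=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out
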