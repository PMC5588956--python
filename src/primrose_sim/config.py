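"""Layered run configuration: cohort spec, risk algorithms, transition
models, economics, threshold and analysis settings, with YAML round trip.

``default_config()`` assembles the synthetic defaults shipped under
``primrose_sim/data`` into a ready-to-run configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .cohort import CohortSpec, default_cohort_spec
from .economics import (DEFAULT_DISCOUNT_RATE, CostSchedule, UtilitySchedule,
                        default_economics)
from .risk import RiskAlgorithm, ThresholdPolicy, default_algorithms
from .transitions import (EffectParameters, ReachModel, SubstateTable,
                          WeibullSurvivalModel, default_transition_models)

__all__ = ["RunConfig", "default_config"]


@dataclass
class RunConfig:
    """Everything needed to run the five-arm analysis."""

    cohort_spec: CohortSpec
    algorithms: dict[str, RiskAlgorithm]
    threshold: ThresholdPolicy
    chd_model: WeibullSurvivalModel
    cva_model: WeibullSurvivalModel
    death_model: WeibullSurvivalModel
    reach: ReachModel
    substates: SubstateTable
    effects: EffectParameters
    costs: CostSchedule
    utilities: UtilitySchedule
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    wtp: tuple[float, ...] = (20000.0, 30000.0)
    horizon: int = 10

    @property
    def transition_models(self) -> dict:
        return {"chd": self.chd_model, "cva": self.cva_model,
                "death_other": self.death_model, "reach": self.reach,
                "substates": self.substates}

    def replace(self, **changes) -> "RunConfig":
        """Pure update — returns a new config, leaving this one unchanged."""
        return dataclasses.replace(self, **changes)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cohort_spec": self.cohort_spec.to_dict(),
            "algorithms": {k: v.to_dict() for k, v in self.algorithms.items()},
            "threshold": self.threshold.threshold,
            "chd_model": self.chd_model.to_dict(),
            "cva_model": self.cva_model.to_dict(),
            "death_model": self.death_model.to_dict(),
            "reach": self.reach.to_dict(),
            "substates": self.substates.to_dict(),
            "effects": dataclasses.asdict(self.effects),
            "costs": self.costs.to_dict(),
            "utilities": self.utilities.to_dict(),
            "discount_rate": self.discount_rate,
            "wtp": list(self.wtp),
            "horizon": self.horizon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            cohort_spec=CohortSpec.from_dict(d["cohort_spec"]),
            algorithms={k: RiskAlgorithm.from_dict(v) for k, v in d["algorithms"].items()},
            threshold=ThresholdPolicy(float(d["threshold"])),
            chd_model=WeibullSurvivalModel.from_dict(d["chd_model"]),
            cva_model=WeibullSurvivalModel.from_dict(d["cva_model"]),
            death_model=WeibullSurvivalModel.from_dict(d["death_model"]),
            reach=ReachModel.from_dict(d["reach"]),
            substates=SubstateTable.from_dict(d["substates"]),
            effects=EffectParameters(**d["effects"]),
            costs=CostSchedule.from_dict(d["costs"]),
            utilities=UtilitySchedule.from_dict(d["utilities"]),
            discount_rate=float(d.get("discount_rate", DEFAULT_DISCOUNT_RATE)),
            wtp=tuple(float(w) for w in d.get("wtp", (20000.0, 30000.0))),
            horizon=int(d.get("horizon", 10)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config(n: int = 1000, seed: int = 0, threshold: float = 0.10) -> RunConfig:
    """The package's synthetic default configuration."""
    models = default_transition_models()
    costs, utilities = default_economics()
    return RunConfig(
        cohort_spec=default_cohort_spec(n=n, seed=seed),
        algorithms=default_algorithms(),
        threshold=ThresholdPolicy(threshold),
        chd_model=models["chd"],
        cva_model=models["cva"],
        death_model=models["death_other"],
        reach=models["reach"],
        substates=models["substates"],
        effects=EffectParameters(),
        costs=costs,
        utilities=utilities,
    )
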