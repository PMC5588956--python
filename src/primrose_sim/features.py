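"""Covariate feature extraction shared by risk algorithms and survival models.

Coefficient sets reference features by name; each feature is either a raw
cohort column or a documented transform of one (dummy coding of categorical
levels, total/HDL cholesterol ratio).  Centering constants, when a model
supplies them, are subtracted before the coefficient is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class MissingCovariateError(KeyError):
    """A model references a covariate the patient data does not provide."""

    def __init__(self, covariate: str, model: str):
        super().__init__(f"covariate {covariate!r} required by model {model!r} is missing")
        self.covariate = covariate
        self.model = model


_DUMMIES = {
    "sex_male": ("sex", "male"),
    "sex_female": ("sex", "female"),
    "smoking_ex": ("smoking", "ex"),
    "smoking_current": ("smoking", "current"),
    "smi_schizophrenia": ("smi_type", "schizophrenia"),
    "smi_bipolar": ("smi_type", "bipolar"),
    "smi_other_psychosis": ("smi_type", "other_psychosis"),
    "smi_registry_only": ("smi_type", "registry_only"),
}

_DIRECT = {
    "age", "sbp", "total_chol", "hdl_chol", "bmi", "weight", "height",
    "antihypertensive", "on_statin_baseline", "diabetes", "heavy_drinking",
    "depression", "antidepressant", "fga", "sga", "townsend", "calendar_year",
}

# Covariates whose value is fixed by model assumption (single vascular bed,
# no CHF/AF, no aspirin): they may appear in coefficient sets but always
# contribute through these constants.
FIXED_ASSUMPTIONS = {
    "vascular_beds": 1.0,
    "chf": 0.0,
    "af": 0.0,
    "aspirin": 0.0,
}


def feature_values(cohort: pd.DataFrame, name: str, model: str = "?") -> np.ndarray:
    """Vectorized feature column for ``name`` over a cohort DataFrame."""
    if name in FIXED_ASSUMPTIONS:
        return np.full(len(cohort), FIXED_ASSUMPTIONS[name])
    if name in _DUMMIES:
        col, level = _DUMMIES[name]
        if col not in cohort.columns:
            raise MissingCovariateError(col, model)
        return (cohort[col].to_numpy() == level).astype(float)
    if name == "chol_ratio":
        for col in ("total_chol", "hdl_chol"):
            if col not in cohort.columns:
                raise MissingCovariateError(col, model)
        return cohort["total_chol"].to_numpy(float) / cohort["hdl_chol"].to_numpy(float)
    if name in _DIRECT:
        if name not in cohort.columns:
            raise MissingCovariateError(name, model)
        return cohort[name].to_numpy(dtype=float)
    raise MissingCovariateError(name, model)


def linear_predictor_frame(
    cohort: pd.DataFrame,
    coefficients: dict[str, float],
    centering: dict[str, float] | None = None,
    model: str = "?",
) -> np.ndarray:
    """LP_i = Σ_j β_j (x_ij − c_j) over a cohort, vectorized."""
    centering = centering or {}
    lp = np.zeros(len(cohort))
    for cov, beta in coefficients.items():
        x = feature_values(cohort, cov, model)
        lp += beta * (x - centering.get(cov, 0.0))
    return lp
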