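"""Synthetic SMI cohort generation.

The source population for the economic model is a UK primary-care sample of
adults (30-74 years) with severe mental illness (SMI) and no prior
cardiovascular disease.  That database cannot be redistributed, so this
module generates synthetic patients whose *marginal* distributions match the
published baseline characteristics table: continuous covariates are drawn
from truncated normals (truncation by redraw, so no point mass at the
bounds), categorical covariates from the published proportions, and BMI is
derived from weight and height so the three stay mutually consistent.

Covariates are drawn independently by default — only marginals are
published.  An optional Gaussian copula accepts a user-supplied correlation
matrix over the continuous covariates for users who have one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ContinuousVar",
    "CategoricalVar",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "summarize_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]


class CohortConfigError(ValueError):
    """Invalid cohort specification (bad probabilities, negative SD, ...)."""


@dataclass(frozen=True)
class ContinuousVar:
    """Truncated-normal marginal: mean/sd with [lo, hi] support (redraw)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise CohortConfigError(f"{name}: SD must be >= 0, got {self.sd}")
        if not self.lo < self.hi:
            raise CohortConfigError(f"{name}: empty truncation range [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class CategoricalVar:
    """Categorical marginal: labels with probabilities summing to 1."""

    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def validate(self, name: str) -> None:
        if len(self.levels) != len(self.probs):
            raise CohortConfigError(f"{name}: {len(self.levels)} levels but {len(self.probs)} probabilities")
        if any(p < 0 for p in self.probs):
            raise CohortConfigError(f"{name}: negative probability")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise CohortConfigError(f"{name}: probabilities sum to {sum(self.probs)!r}, not 1")


def _flag(p: float) -> CategoricalVar:
    return CategoricalVar(("0", "1"), (1.0 - p, p))


# Column order of the cohort CSV / DataFrame.
COHORT_COLUMNS = [
    "id", "age", "sex", "smi_type", "sbp", "antihypertensive",
    "total_chol", "hdl_chol", "on_statin_baseline", "weight", "height",
    "bmi", "diabetes", "smoking", "heavy_drinking", "depression",
    "antidepressant", "fga", "sga", "townsend", "calendar_year",
]

_CONTINUOUS = ("age", "sbp", "total_chol", "hdl_chol", "weight", "height", "calendar_year")
_FLAGS = ("antihypertensive", "on_statin_baseline", "diabetes", "heavy_drinking",
          "depression", "antidepressant", "fga", "sga")


@dataclass
class CohortSpec:
    """Per-variable marginal distributions plus sample size and seed.

    ``continuous`` maps each continuous covariate to a :class:`ContinuousVar`
    and ``categorical`` each discrete covariate to a :class:`CategoricalVar`
    (binary flags use levels ("0", "1")).  ``copula_corr``, if given, is a
    correlation matrix over the continuous covariates in their listed order.
    """

    n: int
    seed: int
    continuous: dict[str, ContinuousVar]
    categorical: dict[str, CategoricalVar]
    copula_corr: np.ndarray | None = None

    def validate(self) -> None:
        if self.n < 0:
            raise CohortConfigError(f"n must be >= 0, got {self.n}")
        for name in _CONTINUOUS:
            if name not in self.continuous:
                raise CohortConfigError(f"missing continuous variable {name!r}")
            self.continuous[name].validate(name)
        for name in ("sex", "smi_type", "smoking", "townsend") + _FLAGS:
            if name not in self.categorical:
                raise CohortConfigError(f"missing categorical variable {name!r}")
            self.categorical[name].validate(name)
        if self.copula_corr is not None:
            k = len(_CONTINUOUS)
            c = np.asarray(self.copula_corr, dtype=float)
            if c.shape != (k, k):
                raise CohortConfigError(f"copula_corr must be {k}x{k}")
            if not np.allclose(c, c.T):
                raise CohortConfigError("copula_corr must be symmetric")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "seed": self.seed,
            "continuous": {k: dataclasses.asdict(v) for k, v in self.continuous.items()},
            "categorical": {
                k: {"levels": list(v.levels), "probs": list(v.probs)}
                for k, v in self.categorical.items()
            },
        }
        if self.copula_corr is not None:
            d["copula_corr"] = np.asarray(self.copula_corr).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            n=int(d["n"]),
            seed=int(d["seed"]),
            continuous={k: ContinuousVar(**v) for k, v in d["continuous"].items()},
            categorical={
                k: CategoricalVar(tuple(v["levels"]), tuple(v["probs"]))
                for k, v in d["categorical"].items()
            },
            copula_corr=np.asarray(d["copula_corr"], dtype=float) if "copula_corr" in d else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_cohort_spec(n: int = 1000, seed: int = 0) -> CohortSpec:
    """Published baseline characteristics of the full eligible SMI cohort
    (N = 33 026).  Categorical proportions are derived from the printed
    counts so each block sums to 1 exactly."""
    N = 33026.0
    return CohortSpec(
        n=n,
        seed=seed,
        continuous={
            "age": ContinuousVar(50.3, 12.0, 30.0, 74.0),
            "sbp": ContinuousVar(128.0, 16.0, 70.0, 250.0),
            "total_chol": ContinuousVar(5.4, 1.1, 1.0, 15.0),
            "hdl_chol": ContinuousVar(1.3, 0.4, 0.4, 5.0),
            "weight": ContinuousVar(80.0, 18.9, 30.0, 250.0),
            "height": ContinuousVar(1.7, 0.1, 1.2, 2.2),
            "calendar_year": ContinuousVar(2007.7, 3.5, 1995.0, 2015.0),
        },
        categorical={
            "sex": CategoricalVar(("male", "female"), (1 - 0.487, 0.487)),
            "smi_type": CategoricalVar(
                ("schizophrenia", "bipolar", "other_psychosis", "registry_only"),
                (11495 / N, 8822 / N, 9098 / N, 3611 / N),
            ),
            "smoking": CategoricalVar(("non", "ex", "current"), (11474 / N, 3726 / N, 17826 / N)),
            "townsend": CategoricalVar(
                ("1", "2", "3", "4", "5"),
                (4886 / N, 5332 / N, 6639 / N, 8048 / N, 8121 / N),
            ),
            "antihypertensive": _flag(0.164),
            "on_statin_baseline": _flag(0.107),
            "diabetes": _flag(0.073),
            "heavy_drinking": _flag(0.143),
            "depression": _flag(0.642),
            "antidepressant": _flag(0.395),
            "fga": _flag(0.151),
            "sga": _flag(0.324),
        },
    )


@lru_cache(maxsize=256)
def _matched_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose [lo, hi]-truncation has the target
    mean and SD.  Truncation shifts and shrinks the raw moments (for age on
    [30, 74] the raw draw would be biased ~+0.6 years), so the parent is
    moment-matched numerically."""
    from scipy import optimize, stats

    def residual(params):
        mu, log_sig = params
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, _ = optimize.fsolve(residual, [mean, np.log(sd)],
                                        xtol=1e-12, full_output=True)
    if ier != 1 or max(abs(r) for r in info["fvec"]) > 1e-6:
        return mean, sd     # target SD infeasible on this interval: raw fallback
    return float(sol[0]), float(np.exp(sol[1]))


def _truncated_normal(rng: np.random.Generator, var: ContinuousVar, n: int) -> np.ndarray:
    """Draw n values by redraw-truncation (no clamping point masses)."""
    if var.sd == 0:
        v = np.full(n, var.mean)
        if n and (var.mean < var.lo or var.mean > var.hi):
            raise CohortConfigError("degenerate mean outside truncation range")
        return v
    mu, sig = _matched_parent(var.mean, var.sd, var.lo, var.hi)
    out = rng.normal(mu, sig, size=n)
    bad = (out < var.lo) | (out > var.hi)
    while bad.any():
        out[bad] = rng.normal(mu, sig, size=int(bad.sum()))
        bad = (out < var.lo) | (out > var.hi)
    return out


def _copula_continuous(rng: np.random.Generator, spec: CohortSpec, n: int) -> dict[str, np.ndarray]:
    """Gaussian-copula draw for the continuous block (marginals preserved via
    per-variable truncated-normal quantile transform)."""
    from scipy import stats

    corr = np.asarray(spec.copula_corr, dtype=float)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(_CONTINUOUS))) @ L.T
    u = stats.norm.cdf(z)
    cols = {}
    for j, name in enumerate(_CONTINUOUS):
        var = spec.continuous[name]
        if var.sd == 0:
            cols[name] = np.full(n, var.mean)
            continue
        mu, sig = _matched_parent(var.mean, var.sd, var.lo, var.hi)
        a = (var.lo - mu) / sig
        b = (var.hi - mu) / sig
        cols[name] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sig)
    return cols


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate ``spec.n`` synthetic patients as a DataFrame.

    Deterministic in ``spec.seed``: the same spec yields a byte-identical
    cohort.  Returns columns :data:`COHORT_COLUMNS`; BMI is weight/height².
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    if spec.copula_corr is not None:
        cont = _copula_continuous(rng, spec, n)
    else:
        cont = {name: _truncated_normal(rng, spec.continuous[name], n) for name in _CONTINUOUS}

    data: dict[str, object] = {"id": np.arange(n, dtype=np.int64)}
    data["age"] = cont["age"]
    for name in ("sex", "smi_type"):
        var = spec.categorical[name]
        data[name] = rng.choice(var.levels, size=n, p=var.probs)
    data["sbp"] = cont["sbp"]
    data["total_chol"] = cont["total_chol"]
    data["hdl_chol"] = cont["hdl_chol"]
    data["weight"] = cont["weight"]
    data["height"] = cont["height"]
    data["bmi"] = data["weight"] / data["height"] ** 2
    var = spec.categorical["smoking"]
    data["smoking"] = rng.choice(var.levels, size=n, p=var.probs)
    for name in _FLAGS:
        var = spec.categorical[name]
        data[name] = (rng.random(n) < var.probs[1]).astype(np.int64)
    var = spec.categorical["townsend"]
    data["townsend"] = rng.choice(var.levels, size=n, p=var.probs).astype(np.int64)
    data["calendar_year"] = np.rint(cont["calendar_year"]).astype(np.int64)

    return pd.DataFrame({c: data[c] for c in COHORT_COLUMNS})


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD for continuous covariates, level proportions for discrete ones,
    laid out one statistic per row (variable, level, statistic, value)."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    rows: list[tuple] = [("n", "", "count", float(len(cohort)))]
    for name in _CONTINUOUS + ("bmi",):
        rows.append((name, "", "mean", float(cohort[name].mean())))
        rows.append((name, "", "sd", float(cohort[name].std(ddof=0))))
    for name in ("sex", "smi_type", "smoking"):
        counts = cohort[name].value_counts(normalize=True)
        for level, p in counts.items():
            rows.append((name, str(level), "proportion", float(p)))
    counts = cohort["townsend"].value_counts(normalize=True)
    for level, p in counts.items():
        rows.append(("townsend", str(level), "proportion", float(p)))
    for name in _FLAGS:
        rows.append((name, "1", "proportion", float(cohort[name].mean())))
    return pd.DataFrame(rows, columns=["variable", "level", "statistic", "value"])


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]
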