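"""Parameter schema, config I/O, age-indexed lookups and PSA sampling.

Every model input — transition-probability fits, fracture incidence curves,
bone-density trajectories, utilities, costs, the discount rate and the
willingness-to-pay threshold — lives in a single validated :class:`ParameterSet`.
Age-dependent quantities are stored as banded tables and resolved to integer
single-year ages with step-function interpolation, matching the model's
one-year cycle length.

Probabilistic-sensitivity-analysis (PSA) distributions are attached by dotted
path into the parameter tree (e.g. ``"costs.dxa"`` or
``"treatment_rr.alendronate.hip"``); :func:`sample_psa` replaces each flagged
scalar by one draw from its distribution and re-validates the result, so a
distribution whose support escapes the parameter's domain is rejected.
"""

from __future__ import annotations

import copy
import math
from pathlib import Path
from typing import Any, Dict, List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, RootModel, field_validator, model_validator

from .errors import ParameterValidationError, RangeError, SchemaError

__all__ = [
    "AgeTable",
    "SurvivalFitSpec",
    "FractureCurve",
    "ZScoreReference",
    "Utilities",
    "Costs",
    "RiskModifiers",
    "DistributionSpec",
    "ParameterSet",
    "load_parameters",
    "write_parameters",
    "sample_psa",
]

CANCER_TRANSITIONS = ("dfs_to_lrs", "dfs_to_crs", "lrs_to_dm", "crs_to_dm", "dm_to_death")
FRACTURE_SITES = ("hip", "vertebral", "other")
DRUGS = ("alendronate", "denosumab", "zoledronate")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AgeTable(RootModel[Dict[int, float]]):
    """Banded age → value table resolved by step interpolation.

    The value for age ``a`` is the entry with the largest key ≤ ``a``; ages
    below the smallest key raise :class:`RangeError`.
    """

    @model_validator(mode="after")
    def _non_empty(self) -> "AgeTable":
        if not self.root:
            raise ValueError("age table must be non-empty")
        return self

    @property
    def min_age(self) -> int:
        return min(self.root)

    def at(self, age: float) -> float:
        keys = sorted(self.root)
        if age < keys[0]:
            raise RangeError(f"age {age} below table start {keys[0]}")
        value = self.root[keys[0]]
        for k in keys:
            if k <= age:
                value = self.root[k]
            else:
                break
        return value

    def as_array(self, age_lo: int, age_hi: int) -> np.ndarray:
        """Dense per-year array covering [age_lo, age_hi] inclusive."""
        return np.array([self.at(a) for a in range(age_lo, age_hi + 1)])


class SurvivalFitSpec(_Strict):
    """Serialized parametric survival fit consumed by the engine."""

    distribution: Literal[
        "exponential", "weibull", "gompertz", "loglogistic", "lognormal", "generalized_gamma"
    ]
    params: Dict[str, float]


class FractureCurve(_Strict):
    """Age-dependent incidence rate curve, rate(age) = a · exp(b · (age − ref_age)).

    ``a`` is the rate (events/person-year) at the reference age for a woman at
    her age-matched reference bone density (Z = 0); ``b`` is the log-linear
    age slope.
    """

    a: float = Field(ge=0)
    b: float
    ref_age: int = 60

    def rate_at(self, age: float) -> float:
        return self.a * math.exp(self.b * (age - self.ref_age))


class ZScoreReference(_Strict):
    """Young-adult and age-matched femoral-neck BMD reference (g/cm²)."""

    young_adult_mean: float = Field(gt=0)
    young_adult_sd: float = Field(gt=0)
    age_mean: AgeTable
    age_sd: AgeTable


class Utilities(_Strict):
    baseline: AgeTable  # age-specific population utility
    cancer_state: Dict[Literal["disease_free", "locoregional_recurrence", "contralateral_recurrence", "distant_metastasis"], float]
    fracture_first_year: Dict[Literal["hip", "vertebral", "other"], float]  # multipliers
    fracture_subsequent: Dict[Literal["hip", "vertebral", "other"], float]  # multipliers
    bedridden: float = Field(ge=-1, le=1)  # absolute utility while bedridden

    @field_validator("cancer_state", "fracture_first_year", "fracture_subsequent")
    @classmethod
    def _in_unit(cls, v: Dict[str, float]) -> Dict[str, float]:
        for key, x in v.items():
            if not (-1.0 <= x <= 1.0):
                raise ValueError(f"utility/multiplier {key}={x} outside [-1, 1]")
        return v

    @model_validator(mode="after")
    def _baseline_in_unit(self) -> "Utilities":
        for age, x in self.baseline.root.items():
            if not (-1.0 <= x <= 1.0):
                raise ValueError(f"baseline utility at age {age} is {x}, outside [-1, 1]")
        return self


class Costs(_Strict):
    """All costs in 2022 USD."""

    drug_annual: Dict[Literal["alendronate", "denosumab", "zoledronate"], float]
    dxa: float = Field(ge=0)
    fracture_acute: Dict[Literal["hip", "vertebral", "other"], float]
    fracture_annual: Dict[Literal["hip", "vertebral", "other"], float]
    long_term_care_annual: float = Field(ge=0)
    indirect_bedridden_annual: float = Field(ge=0)
    indirect_post_fracture_first_year: float = Field(ge=0)

    @field_validator("drug_annual", "fracture_acute", "fracture_annual")
    @classmethod
    def _non_negative(cls, v: Dict[str, float]) -> Dict[str, float]:
        for key, x in v.items():
            if x < 0:
                raise ValueError(f"cost {key}={x} is negative")
        return v


class RiskModifiers(_Strict):
    """Scenario relative risks for high-risk subgroups."""

    prior_fracture_rr: float = Field(gt=0)
    prior_falls_rr: float = Field(gt=0)


class DistributionSpec(_Strict):
    """PSA distribution: family plus hyperparameters.

    Families follow health-economics convention: ``beta(alpha, beta)`` for
    probabilities/utilities, ``gamma(shape, scale)`` for costs and rates,
    ``lognormal(mu, sigma)`` (parameters of log) for relative risks,
    plus ``normal(mu, sd)``, ``uniform(low, high)`` and ``point(value)``.
    """

    family: Literal["beta", "gamma", "lognormal", "normal", "uniform", "point"]
    args: Dict[str, float]

    def draw(self, rng: np.random.Generator) -> float:
        a = self.args
        if self.family == "beta":
            return float(rng.beta(a["alpha"], a["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(a["shape"], a["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(a["mu"], a["sigma"]))
        if self.family == "normal":
            return float(rng.normal(a["mu"], a["sd"]))
        if self.family == "uniform":
            return float(rng.uniform(a["low"], a["high"]))
        return float(a["value"])  # point mass

    def mean(self) -> float:
        a = self.args
        if self.family == "beta":
            return a["alpha"] / (a["alpha"] + a["beta"])
        if self.family == "gamma":
            return a["shape"] * a["scale"]
        if self.family == "lognormal":
            return math.exp(a["mu"] + a["sigma"] ** 2 / 2)
        if self.family == "normal":
            return a["mu"]
        if self.family == "uniform":
            return (a["low"] + a["high"]) / 2
        return a["value"]


class ParameterSet(_Strict):
    """Complete, validated model input set. See module docstring."""

    # cohort / horizon
    start_age: int = Field(ge=40, le=90, default=60)
    max_age: int = Field(default=100, le=110)
    ai_duration_years: int = Field(default=5, ge=0)
    discount_rate: float = Field(ge=0, le=0.2)
    wtp: float = Field(gt=0)
    wtp_high: float = Field(gt=0)
    perspective: Literal["healthcare", "societal"] = "healthcare"
    initial_prior_fracture: bool = False

    # breast-cancer progression (time-dependent transitions)
    cancer_transition_fits: Dict[str, SurvivalFitSpec]

    # fracture epidemiology
    fracture_rate_curves: Dict[Literal["hip", "vertebral", "other"], FractureCurve]
    fracture_gradient: Dict[Literal["hip", "vertebral", "other"], float]  # RR per SD of Z
    rr_subsequent_fracture: Dict[Literal["hip", "vertebral", "other"], float]
    p_bedridden_after_hip: float = Field(ge=0, le=1)
    hip_fracture_mortality_hr: AgeTable
    dm_mortality_hr: float = Field(gt=0, default=1.0)
    background_mortality: AgeTable  # annual death probability, women

    # bone density
    bmd_baseline: AgeTable  # mean femoral-neck T-score by initiation-age band
    bmd_baseline_sd: float = Field(gt=0)  # between-woman SD of baseline T-score
    bmd_loss_on_ai: float = Field(ge=0)  # T-score SD lost per year on AI therapy
    bmd_loss_natural: AgeTable  # T-score SD lost per year off therapy
    zscore_reference: ZScoreReference

    # treatment
    treatment_rr: Dict[Literal["alendronate", "denosumab", "zoledronate"], Dict[Literal["hip", "vertebral", "other"], float]]
    residual_duration_years: Dict[Literal["alendronate", "denosumab", "zoledronate"], float]
    treatment_duration_years: Dict[Literal["alendronate", "denosumab", "zoledronate"], float]
    adherence: float = Field(ge=0, le=1)

    # economics
    utilities: Utilities
    costs: Costs

    # scenarios
    risk_modifiers: RiskModifiers

    # probabilistic sensitivity analysis
    psa_distributions: Dict[str, DistributionSpec] = Field(default_factory=dict)

    @field_validator("treatment_rr")
    @classmethod
    def _rr_positive(cls, v):
        for drug, sites in v.items():
            for site, rr in sites.items():
                if rr <= 0:
                    raise ValueError(f"treatment RR {drug}/{site}={rr} must be > 0")
        return v

    @field_validator("rr_subsequent_fracture", "fracture_gradient")
    @classmethod
    def _positive(cls, v):
        for key, x in v.items():
            if x <= 0:
                raise ValueError(f"relative risk {key}={x} must be > 0")
        return v

    @field_validator("residual_duration_years", "treatment_duration_years")
    @classmethod
    def _non_neg_years(cls, v):
        for key, x in v.items():
            if x < 0:
                raise ValueError(f"duration {key}={x} must be >= 0")
        return v

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        if self.max_age <= self.start_age:
            raise ValueError("max_age must exceed start_age")
        for name in CANCER_TRANSITIONS:
            if name not in self.cancer_transition_fits:
                raise ValueError(f"cancer_transition_fits missing transition '{name}'")
        for table, label in [
            (self.background_mortality, "background_mortality"),
            (self.hip_fracture_mortality_hr, "hip_fracture_mortality_hr"),
            (self.bmd_loss_natural, "bmd_loss_natural"),
            (self.utilities.baseline, "utilities.baseline"),
            (self.zscore_reference.age_mean, "zscore_reference.age_mean"),
            (self.zscore_reference.age_sd, "zscore_reference.age_sd"),
        ]:
            if table.min_age > self.start_age:
                raise ValueError(
                    f"{label} starts at age {table.min_age}, after cohort start {self.start_age}"
                )
        for age, q in self.background_mortality.root.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"background mortality at age {age} is {q}, outside [0, 1]")
        if self.bmd_baseline.min_age > self.start_age:
            raise ValueError("bmd_baseline table does not cover the start age")
        return self

    # -- convenience -------------------------------------------------------

    def copy_deep(self) -> "ParameterSet":
        return self.model_copy(deep=True)

    def get_path(self, path: str) -> Any:
        """Resolve a dotted path (``costs.dxa``) to its scalar value."""
        obj: Any = self
        for part in path.split("."):
            if isinstance(obj, BaseModel) and not isinstance(obj, RootModel):
                if part not in type(obj).model_fields:
                    raise ParameterValidationError(f"unknown parameter path component '{part}' in '{path}'")
                obj = getattr(obj, part)
            elif isinstance(obj, RootModel):
                obj = obj.root[int(part)]
            elif isinstance(obj, dict):
                key: Any = part
                if key not in obj:
                    try:
                        key = int(part)
                    except ValueError:
                        pass
                if key not in obj:
                    raise ParameterValidationError(f"unknown parameter path component '{part}' in '{path}'")
                obj = obj[key]
            else:
                raise ParameterValidationError(f"cannot descend into scalar at '{part}' of '{path}'")
        return obj

    def with_path(self, path: str, value: float) -> "ParameterSet":
        """Return a deep copy with the scalar at ``path`` replaced by ``value``."""
        data = self.model_dump()
        obj: Any = data
        parts = path.split(".")
        for part in parts[:-1]:
            key: Any = part
            if isinstance(obj, dict) and key not in obj:
                try:
                    key = int(part)
                except ValueError:
                    pass
            if not isinstance(obj, dict) or key not in obj:
                raise ParameterValidationError(f"unknown parameter path '{path}'")
            obj = obj[key]
        leaf: Any = parts[-1]
        if isinstance(obj, dict) and leaf not in obj:
            try:
                leaf = int(parts[-1])
            except ValueError:
                pass
        if not isinstance(obj, dict) or leaf not in obj:
            raise ParameterValidationError(f"unknown parameter path '{path}'")
        obj[leaf] = value
        return _validate(data)


def _validate(data: dict) -> ParameterSet:
    try:
        return ParameterSet.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        msg = str(exc)
        if "Field required" in msg or "Extra inputs" in msg:
            raise SchemaError(msg) from exc
        raise ParameterValidationError(msg) from exc


def load_parameters(path: str | Path) -> ParameterSet:
    """Read and validate a YAML parameter file.

    Raises :class:`SchemaError` for missing/unknown fields and
    :class:`ParameterValidationError` for domain violations; both name the
    offending field.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path} does not contain a mapping")
    return _validate(data)


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the canonical YAML form; ``load_parameters`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.model_dump(mode="json"), fh, sort_keys=True)


def sample_psa(params: ParameterSet, seed: int) -> ParameterSet:
    """One second-order draw: replace every PSA-flagged parameter by a sample.

    Deterministic given ``seed``; parameters without a distribution are left
    unchanged. The sampled set is re-validated, so a distribution whose
    support violates the parameter's domain raises
    :class:`ParameterValidationError`.
    """
    if not params.psa_distributions:
        return params.copy_deep()
    rng = np.random.default_rng(seed)
    data = params.model_dump()
    # draw in sorted path order for seed-stable assignment
    for path in sorted(params.psa_distributions):
        dist = params.psa_distributions[path]
        value = dist.draw(rng)
        obj: Any = data
        parts = path.split(".")
        for part in parts[:-1]:
            key: Any = part if part in obj else _maybe_int(part)
            obj = obj[key]
        leaf = parts[-1] if parts[-1] in obj else _maybe_int(parts[-1])
        if leaf not in obj:
            raise ParameterValidationError(f"PSA path '{path}' not found in parameter set")
        obj[leaf] = value
    return _validate(data)


def _maybe_int(s: str) -> Any:
    try:
        return int(s)
    except ValueError:
        return s
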