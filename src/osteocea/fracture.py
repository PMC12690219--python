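"""Age- and BMD-dependent fracture risk, bone-density trajectories and
treatment-effect modification.

Fracture incidence is modelled as an age curve per site (hip, vertebral,
other) scaled by a gradient-of-risk adjustment g^(−Z), where Z is the
femoral-neck Z-score (SD relative to the age-matched reference) and g the
relative risk per SD, and — for women with any prior fragility fracture — by
a site-specific repeat-fracture relative risk, except at the vertebral site,
which is exempt from the repeat-fracture multiplier.

Annual incidence rates r convert to per-cycle probabilities by
p = 1 − exp(−r·t).

Bone density is tracked as a femoral-neck T-score. During aromatase-inhibitor
(AI) therapy the T-score falls at a constant drug-induced rate; off therapy it
follows the age-specific natural loss table. T-scores convert to Z-scores
through the young-adult and age-matched reference means/SDs.

Anti-resorptive treatment multiplies fracture rates by a drug- and
site-specific relative risk while on therapy. Bisphosphonates retain a
residual effect after discontinuation: the relative risk returns linearly to
1 over a configured residual period (equal to the treatment period by
default); drugs with no residual effect revert immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError, InputError, RangeError
from .params import ParameterSet, ZScoreReference

__all__ = [
    "BmdState",
    "FractureRisk",
    "rate_to_probability",
    "update_bmd",
    "tscore_to_zscore",
    "zscore_to_tscore",
    "fracture_rate",
    "treatment_rr",
]


@dataclass(frozen=True)
class BmdState:
    """Femoral-neck T-score (SD units) at a given age."""

    tscore: float
    age: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tscore):
            raise InputError("tscore must be finite")


@dataclass(frozen=True)
class FractureRisk:
    site: str
    annual_rate: float  # events / person-year
    cycle_probability: float

    def __post_init__(self) -> None:
        if self.annual_rate < 0 or not (0.0 <= self.cycle_probability <= 1.0):
            raise InputError("invalid fracture risk")


def rate_to_probability(rate: float, interval: float = 1.0) -> float:
    """p = 1 − exp(−r·t): probability of ≥1 event in ``interval`` years."""
    if rate < 0:
        raise InputError(f"rate must be >= 0, got {rate}")
    if interval <= 0:
        raise InputError(f"interval must be > 0, got {interval}")
    return -math.expm1(-rate * interval)


def update_bmd(bmd: BmdState, on_ai: bool, params: ParameterSet) -> BmdState:
    """Advance one cycle: apply AI-induced or natural age-specific T-score loss."""
    loss = params.bmd_loss_on_ai if on_ai else params.bmd_loss_natural.at(bmd.age)
    return BmdState(tscore=bmd.tscore - loss, age=bmd.age + 1)


def tscore_to_zscore(bmd: BmdState, reference: ZScoreReference) -> float:
    """Z = (BMD implied by T − age-matched mean) / age-matched SD."""
    absolute = reference.young_adult_mean + bmd.tscore * reference.young_adult_sd
    mean = reference.age_mean.at(bmd.age)
    sd = reference.age_sd.at(bmd.age)
    return (absolute - mean) / sd


def zscore_to_tscore(z: float, age: float, reference: ZScoreReference) -> float:
    """Inverse of :func:`tscore_to_zscore` (round-trips to machine precision)."""
    absolute = reference.age_mean.at(age) + z * reference.age_sd.at(age)
    return (absolute - reference.young_adult_mean) / reference.young_adult_sd


def fracture_rate(
    site: str,
    bmd: BmdState,
    any_prior_fracture: bool,
    params: ParameterSet,
) -> FractureRisk:
    """Annual fracture rate and per-cycle probability for one site.

    rate = age-curve(site, age) · g^(−Z) · RR_repeat, where RR_repeat applies
    only with a prior fracture and only at non-vertebral sites.
    """
    if site not in params.fracture_rate_curves:
        raise InputError(f"unknown fracture site '{site}'")
    curve = params.fracture_rate_curves[site]
    base = curve.rate_at(bmd.age)
    z = tscore_to_zscore(bmd, params.zscore_reference)
    g = params.fracture_gradient[site]
    rate = base * g ** (-z)
    if any_prior_fracture and site != "vertebral":
        rate *= params.rr_subsequent_fracture[site]
    return FractureRisk(site=site, annual_rate=rate, cycle_probability=rate_to_probability(rate))


def treatment_rr(
    drug: str,
    site: str,
    years_since_stop: float,
    params: ParameterSet,
) -> float:
    """Relative risk of fracture under treatment, including residual decay.

    ``years_since_stop`` ≤ 0 means on treatment (full effect). After
    discontinuation the RR rises linearly from the on-treatment value to 1
    over ``residual_duration_years[drug]`` (continuous at the stop time),
    reaching exactly 1 at the end of the residual period; a zero residual
    duration reverts to 1 immediately.
    """
    if drug not in params.treatment_rr:
        raise ConfigError(f"drug '{drug}' not configured")
    rr = params.treatment_rr[drug][site]
    if years_since_stop <= 0:
        return rr
    residual = params.residual_duration_years[drug]
    if residual <= 0 or years_since_stop >= residual:
        return 1.0
    return rr + (1.0 - rr) * (years_since_stop / residual)
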