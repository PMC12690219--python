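"""Synthetic inputs with known ground truth: the default parameter fixture,
Kaplan–Meier curves sampled from known distributions, and toy cohorts.

The default :class:`~osteocea.params.ParameterSet` emulates the structure of a
full model-input table. Constants printed in the study design — the 5%
discount rate, the $38 223/QALY willingness-to-pay threshold (3 × 2022 China
GDP per capita, $50 964 for 4×), drug courses of 5/5/3 years, a 60-year-old
cohort on 5 years of AI therapy — are set exactly. Every other value (fracture
incidence curves, costs, utilities, BMD trajectories, PSA hyperparameters) is
a plausible synthetic stand-in chosen from the health-economics and
osteoporosis literature's typical magnitudes, tagged ``synthetic_stand_in`` in
the :class:`FixtureManifest`. Stand-ins were chosen once so that the fixture
reproduces the qualitative structure of the problem — a 10-year any-fracture
cumulative incidence near 13% under 5 years of AI exposure, and
cost-effectiveness improving with initiation age — without asserting that any
individual stand-in equals the unpublished source value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .engine import PatientState, RngStreams, _CH_ADH, _CH_BMD
from .errors import ConfigError, InputError
from .params import ParameterSet, load_parameters, write_parameters
from .survival import KMCurve, SurvivalFit, _gengamma_scipy

__all__ = [
    "FixtureManifest",
    "make_default_params",
    "default_parameters",
    "default_dsa_ranges",
    "write_fixtures",
    "make_km",
    "make_toy_cohort",
]

FIXTURE_VERSION = 1


@dataclass
class FixtureManifest:
    """Per-parameter provenance: paper_main_text | synthetic_stand_in."""

    version: int
    provenance: Dict[str, str]
    seeds: Dict[str, int] = field(default_factory=dict)

    def covers(self, params: ParameterSet) -> bool:
        return all(name in self.provenance for name in type(params).model_fields)


def make_default_params() -> Tuple[ParameterSet, FixtureManifest]:
    """Build the default parameter fixture and its provenance manifest."""
    ages = range(60, 102)
    background_mortality = {a: round(0.0068 * math.exp(0.098 * (a - 60)), 6) for a in ages}
    age_mean_bmd = {a: round(0.728 - 0.0055 * (a - 60), 5) for a in ages}
    fx_a = {"hip": 0.00089, "vertebral": 0.00444, "other": 0.0037}

    data = dict(
        start_age=60,
        max_age=100,
        ai_duration_years=5,
        discount_rate=0.05,
        wtp=38223.0,
        wtp_high=50964.0,
        perspective="healthcare",
        initial_prior_fracture=False,
        cancer_transition_fits={
            "dfs_to_lrs": {"distribution": "lognormal", "params": {"mu": 4.0, "sigma": 1.4}},
            "dfs_to_crs": {"distribution": "lognormal", "params": {"mu": 5.0, "sigma": 1.5}},
            "lrs_to_dm": {"distribution": "lognormal", "params": {"mu": 2.2, "sigma": 1.2}},
            "crs_to_dm": {"distribution": "lognormal", "params": {"mu": 2.6, "sigma": 1.3}},
            "dm_to_death": {"distribution": "lognormal", "params": {"mu": 1.55, "sigma": 0.9}},
        },
        fracture_rate_curves={
            "hip": {"a": fx_a["hip"], "b": 0.10, "ref_age": 60},
            "vertebral": {"a": fx_a["vertebral"], "b": 0.045, "ref_age": 60},
            "other": {"a": fx_a["other"], "b": 0.025, "ref_age": 60},
        },
        fracture_gradient={"hip": 2.6, "vertebral": 1.8, "other": 1.5},
        rr_subsequent_fracture={"hip": 2.0, "vertebral": 1.0, "other": 1.8},
        p_bedridden_after_hip=0.10,
        hip_fracture_mortality_hr={60: 2.8, 70: 2.4, 80: 2.0, 90: 1.6},
        dm_mortality_hr=1.0,
        background_mortality=background_mortality,
        bmd_baseline={60: -1.2, 65: -1.5, 70: -1.8, 75: -2.1},
        bmd_baseline_sd=1.0,
        bmd_loss_on_ai=0.13,
        bmd_loss_natural={60: 0.036, 70: 0.045, 80: 0.050},
        zscore_reference={
            "young_adult_mean": 0.86,
            "young_adult_sd": 0.11,
            "age_mean": age_mean_bmd,
            "age_sd": {a: 0.11 for a in ages},
        },
        treatment_rr={
            "alendronate": {"hip": 0.60, "vertebral": 0.55, "other": 0.81},
            "denosumab": {"hip": 0.60, "vertebral": 0.32, "other": 0.80},
            "zoledronate": {"hip": 0.59, "vertebral": 0.30, "other": 0.75},
        },
        residual_duration_years={"alendronate": 5.0, "denosumab": 0.0, "zoledronate": 3.0},
        treatment_duration_years={"alendronate": 5.0, "denosumab": 5.0, "zoledronate": 3.0},
        adherence=0.90,
        utilities={
            "baseline": {60: 0.91, 70: 0.87, 80: 0.81, 90: 0.75},
            "cancer_state": {
                "disease_free": 0.94,
                "locoregional_recurrence": 0.85,
                "contralateral_recurrence": 0.85,
                "distant_metastasis": 0.65,
            },
            "fracture_first_year": {"hip": 0.70, "vertebral": 0.82, "other": 0.91},
            "fracture_subsequent": {"hip": 0.90, "vertebral": 0.93, "other": 1.0},
            "bedridden": 0.28,
        },
        costs={
            "drug_annual": {"alendronate": 65.0, "denosumab": 440.0, "zoledronate": 75.0},
            "dxa": 26.2,
            "fracture_acute": {"hip": 4900.0, "vertebral": 2600.0, "other": 1500.0},
            "fracture_annual": {"hip": 390.0, "vertebral": 150.0, "other": 60.0},
            "long_term_care_annual": 3100.0,
            "indirect_bedridden_annual": 1560.0,
            "indirect_post_fracture_first_year": 720.0,
        },
        risk_modifiers={"prior_fracture_rr": 1.8, "prior_falls_rr": 1.6},
        psa_distributions={
            "adherence": {"family": "beta", "args": {"alpha": 36.0, "beta": 4.0}},
            "p_bedridden_after_hip": {"family": "beta", "args": {"alpha": 10.0, "beta": 90.0}},
            "treatment_rr.alendronate.hip": {"family": "lognormal", "args": {"mu": math.log(0.60), "sigma": 0.12}},
            "treatment_rr.alendronate.vertebral": {"family": "lognormal", "args": {"mu": math.log(0.55), "sigma": 0.12}},
            "treatment_rr.alendronate.other": {"family": "lognormal", "args": {"mu": math.log(0.81), "sigma": 0.10}},
            "rr_subsequent_fracture.hip": {"family": "lognormal", "args": {"mu": math.log(2.0), "sigma": 0.15}},
            "rr_subsequent_fracture.other": {"family": "lognormal", "args": {"mu": math.log(1.8), "sigma": 0.15}},
            "bmd_loss_on_ai": {"family": "gamma", "args": {"shape": 25.0, "scale": 0.13 / 25.0}},
            "fracture_rate_curves.hip.a": {"family": "gamma", "args": {"shape": 25.0, "scale": fx_a["hip"] / 25.0}},
            "fracture_rate_curves.vertebral.a": {"family": "gamma", "args": {"shape": 25.0, "scale": fx_a["vertebral"] / 25.0}},
            "fracture_rate_curves.other.a": {"family": "gamma", "args": {"shape": 25.0, "scale": fx_a["other"] / 25.0}},
            "costs.drug_annual.alendronate": {"family": "gamma", "args": {"shape": 25.0, "scale": 65.0 / 25.0}},
            "costs.dxa": {"family": "gamma", "args": {"shape": 25.0, "scale": 26.2 / 25.0}},
            "costs.fracture_acute.hip": {"family": "gamma", "args": {"shape": 25.0, "scale": 4900.0 / 25.0}},
            "costs.fracture_acute.vertebral": {"family": "gamma", "args": {"shape": 25.0, "scale": 2600.0 / 25.0}},
            "costs.fracture_acute.other": {"family": "gamma", "args": {"shape": 25.0, "scale": 1500.0 / 25.0}},
            "costs.long_term_care_annual": {"family": "gamma", "args": {"shape": 25.0, "scale": 3100.0 / 25.0}},
            "utilities.bedridden": {"family": "beta", "args": {"alpha": 14.0, "beta": 36.0}},
            "utilities.fracture_first_year.hip": {"family": "beta", "args": {"alpha": 42.0, "beta": 18.0}},
            "utilities.fracture_first_year.vertebral": {"family": "beta", "args": {"alpha": 49.2, "beta": 10.8}},
            "utilities.fracture_first_year.other": {"family": "beta", "args": {"alpha": 54.6, "beta": 5.4}},
        },
    )
    params = ParameterSet.model_validate(data)

    main_text = {
        "start_age", "ai_duration_years", "discount_rate", "wtp", "wtp_high",
        "perspective", "treatment_duration_years", "initial_prior_fracture",
        "bmd_loss_on_ai",
    }
    provenance = {
        name: ("paper_main_text" if name in main_text else "synthetic_stand_in")
        for name in type(params).model_fields
    }
    manifest = FixtureManifest(version=FIXTURE_VERSION, provenance=provenance,
                               seeds={"fixture": 0})
    return params, manifest


def default_dsa_ranges(params: ParameterSet) -> Dict[str, Tuple[float, float]]:
    """One-way sensitivity ranges for the tornado analysis (±25% or domain)."""
    return {
        "discount_rate": (0.0, 0.08),
        "adherence": (0.54, 1.0),
        "p_bedridden_after_hip": (0.05, 0.15),
        "bmd_loss_on_ai": (0.13 * 0.75, 0.13 * 1.25),
        "treatment_rr.alendronate.hip": (0.48, 0.75),
        "utilities.fracture_first_year.hip": (0.60, 0.80),
        "costs.drug_annual.alendronate": (65.0 * 0.75, 65.0 * 1.25),
        "costs.dxa": (26.2 * 0.75, 26.2 * 1.25),
        "costs.fracture_acute.hip": (4900.0 * 0.75, 4900.0 * 1.25),
        "fracture_rate_curves.hip.a": (0.00089 * 0.75, 0.00089 * 1.25),
    }


def _fixture_dir() -> Path:
    return Path(str(resources.files("osteocea").joinpath("fixtures")))


def default_parameters() -> ParameterSet:
    """Load the shipped default fixture file."""
    return load_parameters(_fixture_dir() / "default_params.yaml")


def write_fixtures(directory: str | Path, seed: int = 0) -> None:
    """Regenerate the fixture files (bit-identical given version and seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params, manifest = make_default_params()
    manifest.seeds["fixture"] = seed
    write_parameters(params, directory / "default_params.yaml")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(
            {"version": manifest.version, "provenance": manifest.provenance, "seeds": manifest.seeds},
            fh, indent=1, sort_keys=True,
        )


# ---------------------------------------------------------------------------
# synthetic Kaplan–Meier curves
# ---------------------------------------------------------------------------


def _sample_times(distribution: str, dist_params: Dict[str, float], n: int,
                  rng: np.random.Generator) -> np.ndarray:
    p = dist_params
    u = rng.random(n)
    if distribution == "exponential":
        return -np.log(u) / p["rate"]
    if distribution == "weibull":
        return p["scale"] * (-np.log(u)) ** (1.0 / p["shape"])
    if distribution == "gompertz":
        a, b = p["rate"], p["shape"]
        if abs(b) < 1e-12:
            return -np.log(u) / a
        arg = 1.0 - b * np.log(u) / a
        t = np.full(n, np.inf)
        ok = arg > 0
        t[ok] = np.log(arg[ok]) / b  # defective tail (b<0) never fails
        return t
    if distribution == "loglogistic":
        return p["scale"] * ((1.0 - u) / u) ** (1.0 / p["shape"])
    if distribution == "lognormal":
        return np.exp(p["mu"] + p["sigma"] * rng.standard_normal(n))
    if distribution == "generalized_gamma":
        return _gengamma_scipy(p["mu"], p["sigma"], p["q"]).rvs(size=n, random_state=rng)
    raise ConfigError(f"unknown distribution '{distribution}'")


def make_km(
    distribution: str,
    dist_params: Dict[str, float],
    n: int,
    censor_time: float,
    grid: float = 0.25,
    seed: int = 0,
) -> Tuple[KMCurve, SurvivalFit]:
    """Simulate event times, digitize the KM estimate, return curve + truth.

    ``grid`` is the digitization spacing in years; the numbers-at-risk table
    is tabulated at integer years. The returned :class:`SurvivalFit` holds the
    generating parameters for recovery tests.
    """
    if n < 10:
        raise InputError("n must be >= 10")
    rng = np.random.default_rng(seed)
    times = _sample_times(distribution, dist_params, n, rng)
    events = times <= censor_time
    obs = np.minimum(times, censor_time)

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(obs, event_observed=events)
    grid_times = np.arange(0.0, censor_time + grid / 2, grid)
    surv = kmf.survival_function_at_times(grid_times).to_numpy()
    risk_times = np.arange(0.0, censor_time + 0.5, 1.0)
    risk = [(float(rt), int(np.sum(obs >= rt))) for rt in risk_times]
    curve = KMCurve(times=grid_times, survival=surv, risk_table=risk,
                    total_events=int(events.sum()))
    truth = SurvivalFit(distribution, dict(dist_params))
    return curve, truth


def make_toy_cohort(
    n: int,
    params: Optional[ParameterSet] = None,
    seed: int = 0,
    tscore_override: Optional[float] = None,
) -> List[PatientState]:
    """Initial patient states drawn exactly as the engine would draw them."""
    if n < 1:
        raise InputError("n must be >= 1")
    if params is None:
        params, _ = make_default_params()
    streams = RngStreams(seed)
    z = streams.normal(_CH_BMD, n)
    base = params.bmd_baseline.at(params.start_age)
    tscores = (np.full(n, tscore_override, dtype=float) if tscore_override is not None
               else base + params.bmd_baseline_sd * z)
    return [
        PatientState(age=float(params.start_age), cycle=0, tscore=float(tscores[i]))
        for i in range(n)
    ]
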