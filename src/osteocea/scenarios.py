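"""Scenario grid: initiation age bands, high-risk subgroups, screening
intervals, adherence, alternative drugs, societal perspective, short horizon.

:func:`apply_scenario` is pure — it returns a modified deep copy of the base
:class:`ParameterSet` plus a dictionary of strategy-level modifications
(drug, screening interval, horizon) that the caller feeds into
:func:`scenario_run` or its own pipeline. The identity scenario is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Literal, Optional, Tuple

from .economics import CEAResult, frontier
from .engine import StrategyOutcome, run_cohort
from .errors import ConfigError, InputError
from .params import ParameterSet
from .strategies import StrategySpec, builtin_strategies, scenario_strategies

__all__ = ["ScenarioSpec", "apply_scenario", "scenario_run"]

AGE_BANDS = {"60-64": 60, "65-69": 65, "70-74": 70, "75-79": 75}


@dataclass(frozen=True)
class ScenarioSpec:
    start_age_band: Literal["60-64", "65-69", "70-74", "75-79"] = "60-64"
    risk_modifier: Literal["none", "prior_fracture", "prior_falls"] = "none"
    adherence_override: Optional[float] = None
    drug_override: Optional[Literal["alendronate", "denosumab", "zoledronate"]] = None
    perspective: Literal["healthcare", "societal"] = "healthcare"
    horizon: Literal["lifetime", "10y"] = "lifetime"
    screening_interval_override: Optional[int] = None  # 2 or 5

    def __post_init__(self) -> None:
        if self.adherence_override is not None and not (0 <= self.adherence_override <= 1):
            raise InputError("adherence_override must be in [0, 1]")
        if self.screening_interval_override not in (None, 2, 5):
            raise InputError("screening interval override must be 2 or 5")


def apply_scenario(base: ParameterSet, spec: ScenarioSpec) -> Tuple[ParameterSet, Dict[str, object]]:
    """Return (modified parameters, strategy modifications) for a scenario.

    The base ParameterSet is never mutated. Strategy modifications carry keys
    ``drug``, ``screening_interval`` and ``horizon`` where overridden.
    """
    params = base.copy_deep()
    mods: Dict[str, object] = {"horizon": "lifetime" if spec.horizon == "lifetime" else 10}

    start_age = AGE_BANDS[spec.start_age_band]
    if start_age != base.start_age:
        params.start_age = start_age  # baseline BMD follows via the banded table

    if spec.risk_modifier != "none":
        rr = (
            base.risk_modifiers.prior_fracture_rr
            if spec.risk_modifier == "prior_fracture"
            else base.risk_modifiers.prior_falls_rr
        )
        for site in params.fracture_rate_curves:
            params.fracture_rate_curves[site].a *= rr
        if spec.risk_modifier == "prior_fracture":
            params.initial_prior_fracture = True

    if spec.adherence_override is not None:
        params.adherence = spec.adherence_override
    if spec.perspective == "societal":
        params.perspective = "societal"
    if spec.drug_override is not None:
        if spec.drug_override not in base.treatment_rr:
            raise ConfigError(f"drug override '{spec.drug_override}' not configured")
        mods["drug"] = spec.drug_override
    if spec.screening_interval_override is not None:
        mods["screening_interval"] = spec.screening_interval_override
    return params, mods


def _strategies_for(mods: Dict[str, object]) -> List[StrategySpec]:
    drug = str(mods.get("drug", "alendronate"))
    strategies = builtin_strategies(drug=drug)
    interval = mods.get("screening_interval")
    if interval is not None:
        strategies = [s for s in strategies if s.screening != "periodic"]
        strategies += scenario_strategies(int(interval), drug=drug)
    return strategies


def scenario_run(
    base: ParameterSet,
    spec: ScenarioSpec,
    n: int,
    seed: int,
    strategies: Optional[List[StrategySpec]] = None,
) -> Tuple[List[StrategyOutcome], CEAResult]:
    """Full scenario pipeline: apply, simulate every strategy, build frontier."""
    params, mods = apply_scenario(base, spec)
    if strategies is None:
        strategies = _strategies_for(mods)
    horizon = mods["horizon"]
    outcomes = [
        run_cohort(n, s, params, seed=seed, horizon=horizon, keep_patients=False)
        for s in strategies
    ]
    return outcomes, frontier(outcomes, wtp=params.wtp)
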