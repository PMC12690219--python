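"""Fracture-prevention strategies: screening schedules and treatment rules.

Six base strategies are compared: no intervention; one-time DXA screening
with selective therapy at the osteoporosis (T ≤ −2.5) or osteopenia
(T ≤ −1.0) threshold; annual DXA screening at either threshold; and universal
therapy without screening. Scenario variants swap the screening interval
(biennial, quinquennial) or the drug (denosumab, zoledronate).

Screening measures the model T-score without error. Periodic screening runs
on cycles 0, k, 2k, … while AI therapy is ongoing (through its final year)
and stops once treatment starts; one treatment course per lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Union

from .errors import ConfigError, InputError
from .params import ParameterSet

__all__ = ["StrategySpec", "Decision", "builtin_strategies", "scenario_strategies", "decide", "get_strategy"]

Threshold = Union[float, Literal["universal", "never"]]

OSTEOPOROSIS = -2.5
OSTEOPENIA = -1.0


@dataclass(frozen=True)
class StrategySpec:
    """Screening schedule + treatment-eligibility threshold + drug + adherence."""

    name: str
    screening: Literal["none", "once", "periodic"]
    treat_threshold: Threshold  # T-score cutoff, or "universal"/"never"
    drug: Optional[Literal["alendronate", "denosumab", "zoledronate"]] = "alendronate"
    interval: Optional[int] = None  # years, for periodic screening
    treatment_duration: Optional[float] = None  # years; None → per-drug default
    adherence: Optional[float] = None  # None → ParameterSet.adherence

    def __post_init__(self) -> None:
        if self.screening == "none" and self.treat_threshold not in ("universal", "never"):
            raise InputError("screening 'none' requires a universal or never threshold")
        if self.screening != "none" and self.treat_threshold in ("universal", "never"):
            raise InputError("screening strategies need a numeric T-score threshold")
        if self.screening == "periodic" and (self.interval is None or self.interval < 1):
            raise InputError("periodic screening requires interval >= 1")
        if self.treat_threshold != "never" and self.drug is None:
            raise InputError("treating strategies must name a drug")
        if self.adherence is not None and not (0.0 <= self.adherence <= 1.0):
            raise InputError("adherence must be in [0, 1]")

    def duration(self, params: ParameterSet) -> float:
        if self.treat_threshold == "never":
            return 0.0
        if self.treatment_duration is not None:
            return self.treatment_duration
        if self.drug not in params.treatment_duration_years:
            raise ConfigError(f"drug '{self.drug}' has no configured duration")
        return params.treatment_duration_years[self.drug]

    def screens_at(self, cycle: int, ai_duration: int) -> bool:
        """Whether the schedule calls for a DXA scan at this cycle."""
        if self.screening == "once":
            return cycle == 0
        if self.screening == "periodic":
            return cycle <= ai_duration and cycle % self.interval == 0
        return False


@dataclass(frozen=True)
class Decision:
    screen: bool
    start_treatment: bool
    dxa_cost_incurred: bool


def builtin_strategies(drug: str = "alendronate") -> List[StrategySpec]:
    """The six base strategies compared in the analysis."""
    return [
        StrategySpec("no_intervention", "none", "never", drug=None),
        StrategySpec("once_osteoporosis", "once", OSTEOPOROSIS, drug=drug),
        StrategySpec("once_osteopenia", "once", OSTEOPENIA, drug=drug),
        StrategySpec("annual_osteoporosis", "periodic", OSTEOPOROSIS, drug=drug, interval=1),
        StrategySpec("annual_osteopenia", "periodic", OSTEOPENIA, drug=drug, interval=1),
        StrategySpec("universal", "none", "universal", drug=drug),
    ]


def scenario_strategies(interval: int, drug: str = "alendronate") -> List[StrategySpec]:
    """Periodic-screening variants (biennial/quinquennial) at both thresholds."""
    return [
        StrategySpec(f"every{interval}y_osteoporosis", "periodic", OSTEOPOROSIS, drug=drug, interval=interval),
        StrategySpec(f"every{interval}y_osteopenia", "periodic", OSTEOPENIA, drug=drug, interval=interval),
    ]


def get_strategy(name: str, strategies: Optional[List[StrategySpec]] = None) -> StrategySpec:
    pool = strategies if strategies is not None else builtin_strategies()
    for s in pool:
        if s.name == name:
            return s
    raise ConfigError(f"unknown strategy '{name}'")


def decide(
    strategy: StrategySpec,
    tscore: float,
    cycle: int,
    treatment_started: bool,
    screened_out_once: bool,
    ai_duration: int = 5,
) -> Decision:
    """Screening/treatment decision for one patient at one cycle.

    ``treatment_started`` — a course was ever begun (active, completed or
    non-adherent); no re-screening or re-treatment afterwards.
    ``screened_out_once`` — a one-time screen already happened (negative),
    so a "once" schedule never screens again.
    """
    if strategy.treat_threshold == "never":
        return Decision(False, False, False)
    if strategy.treat_threshold == "universal":
        return Decision(False, cycle == 0 and not treatment_started, False)
    if treatment_started:
        return Decision(False, False, False)
    if strategy.screening == "once" and screened_out_once:
        return Decision(False, False, False)
    if not strategy.screens_at(cycle, ai_duration):
        return Decision(False, False, False)
    treat = tscore <= float(strategy.treat_threshold)
    return Decision(True, treat, True)
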