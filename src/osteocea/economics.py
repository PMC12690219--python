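"""Cost-effectiveness analysis: ICERs, the efficiency frontier, probabilistic
sensitivity analysis (CEAC) and one-way deterministic sensitivity (tornado).

The incremental cost-effectiveness ratio between two strategies is
ICER = Δcost / ΔQALY. Strategies are ranked on the efficiency frontier after
removing strictly dominated options (costlier and no more effective) and
extendedly dominated ones (beaten by a convex combination of two others —
equivalently, options whose ICER against the previous frontier member exceeds
the ICER of the next); frontier ICERs are non-decreasing.

The probabilistic sensitivity analysis draws each flagged parameter from its
distribution (second-order Monte Carlo), re-runs a reduced first-order cohort
per draw with common random numbers, and reports the cost-effectiveness
acceptability curve: for each willingness-to-pay λ, the fraction of draws in
which each strategy maximises net monetary benefit NMB = λ·QALY − cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import StrategyOutcome, run_cohort
from .errors import InputError, UndefinedIcer
from .params import ParameterSet, sample_psa
from .strategies import StrategySpec

__all__ = [
    "CEAResult",
    "icer",
    "compare",
    "frontier",
    "net_monetary_benefit",
    "psa",
    "tornado",
    "default_wtp_grid",
]


@dataclass
class CEAResult:
    """Efficiency frontier with pairwise ICERs and dominated strategies."""

    frontier: List[Tuple[str, Optional[float]]]  # (name, ICER vs previous member; None for anchor); ICERs non-decreasing, ties = collinear members
    dominated: List[Tuple[str, str]]  # (name, "strict" | "extended")
    wtp: Optional[float] = None
    cost_effective: Optional[str] = None  # frontier member chosen at the wtp


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """ICER of ``b`` relative to ``a``: (cost_b − cost_a)/(qaly_b − qaly_a).

    Raises :class:`UndefinedIcer` when ΔQALY = 0. A dominant ``b`` (cheaper
    and more effective) yields a negative value; use :func:`compare` to get
    dominance flagged explicitly.
    """
    dq = b.mean_qaly - a.mean_qaly
    if dq == 0:
        raise UndefinedIcer(f"{b.strategy} vs {a.strategy}: identical QALYs")
    return (b.mean_cost - a.mean_cost) / dq


def compare(a: StrategyOutcome, b: StrategyOutcome) -> Dict[str, object]:
    """Pairwise comparison of ``b`` against ``a`` with dominance flags."""
    dc = b.mean_cost - a.mean_cost
    dq = b.mean_qaly - a.mean_qaly
    dominant = dc <= 0 and dq >= 0 and (dc < 0 or dq > 0)
    dominated = dc >= 0 and dq <= 0 and (dc > 0 or dq < 0)
    value = None if dq == 0 else dc / dq
    return {"delta_cost": dc, "delta_qaly": dq, "icer": value,
            "dominant": dominant, "dominated": dominated}


def frontier(outcomes: Sequence[StrategyOutcome], wtp: Optional[float] = None) -> CEAResult:
    """Efficiency frontier by iterative strict/extended dominance removal.

    Returns frontier members in cost order, each with its ICER against the
    previous member (non-decreasing; collinear options are kept). With ``wtp`` given, also reports
    the highest-QALY frontier member whose ICER is at or below the threshold.
    """
    if len(outcomes) < 2:
        raise InputError("frontier needs at least 2 outcomes")
    items = sorted(outcomes, key=lambda o: (o.mean_cost, o.mean_qaly))
    dominated: List[Tuple[str, str]] = []

    # strict dominance: costlier and not more effective than someone else
    survivors = []
    for o in items:
        if any(
            (p.mean_cost <= o.mean_cost and p.mean_qaly >= o.mean_qaly)
            and (p.mean_cost < o.mean_cost or p.mean_qaly > o.mean_qaly)
            for p in items
            if p is not o
        ):
            dominated.append((o.strategy, "strict"))
        else:
            survivors.append(o)

    # extended dominance: remove members that break ICER monotonicity
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        icers = [
            (survivors[i + 1].mean_cost - survivors[i].mean_cost)
            / (survivors[i + 1].mean_qaly - survivors[i].mean_qaly)
            for i in range(len(survivors) - 1)
        ]
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:  # collinear members stay on the frontier
                dominated.append((survivors[i + 1].strategy, "extended"))
                survivors.pop(i + 1)
                changed = True
                break
    front: List[Tuple[str, Optional[float]]] = [(survivors[0].strategy, None)]
    for prev, cur in zip(survivors, survivors[1:]):
        front.append((cur.strategy, (cur.mean_cost - prev.mean_cost) / (cur.mean_qaly - prev.mean_qaly)))

    chosen = None
    if wtp is not None:
        chosen = front[0][0]
        for name, ic in front[1:]:
            if ic is not None and ic <= wtp:
                chosen = name
    return CEAResult(frontier=front, dominated=dominated, wtp=wtp, cost_effective=chosen)


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    return outcome.mean_qaly * wtp - outcome.mean_cost


def default_wtp_grid(wtp: float = 38223.0, wtp_high: float = 50964.0) -> np.ndarray:
    """0 → 80 000 $/QALY in $80 steps plus the two landmark thresholds."""
    grid = np.arange(0.0, 80000.0 + 1, 80.0)
    return np.unique(np.concatenate([grid, [wtp, wtp_high]]))


def psa(
    params: ParameterSet,
    strategies: Sequence[StrategySpec],
    n_outer: int,
    n_inner: int,
    seed: int,
    horizon="lifetime",
    wtp_grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Second-order Monte Carlo → cost-effectiveness acceptability curves.

    Returns a DataFrame indexed by WTP with one probability column per
    strategy; rows sum to 1. Within each outer draw all strategies share one
    inner first-order seed (common random numbers). NMB ties (probability
    zero for continuous draws) go to the earlier strategy in the list.
    """
    if n_outer < 1:
        raise InputError("n_outer must be >= 1")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(params.wtp, params.wtp_high)
    rng = np.random.default_rng(seed)
    names = [s.name for s in strategies]
    wins = np.zeros((len(wtp_grid), len(names)))
    for _ in range(n_outer):
        psa_seed = int(rng.integers(0, 2**31 - 1))
        inner_seed = int(rng.integers(0, 2**31 - 1))
        drawn = sample_psa(params, psa_seed)
        costs = np.empty(len(names))
        qalys = np.empty(len(names))
        for j, strat in enumerate(strategies):
            out = run_cohort(n_inner, strat, drawn, seed=inner_seed, horizon=horizon,
                             keep_patients=False)
            costs[j] = out.mean_cost
            qalys[j] = out.mean_qaly
        nmb = np.outer(wtp_grid, qalys) - costs[None, :]
        wins[np.arange(len(wtp_grid)), np.argmax(nmb, axis=1)] += 1.0
    ceac = pd.DataFrame(wins / n_outer, index=pd.Index(wtp_grid, name="wtp"), columns=names)
    return ceac


def tornado(
    params: ParameterSet,
    strategy_pair: Tuple[StrategySpec, StrategySpec],
    ranges: Dict[str, Tuple[float, float]],
    n: int,
    seed: int,
    horizon="lifetime",
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis of a pairwise ICER.

    For each parameter path, the ICER of ``strategy_pair[1]`` vs
    ``strategy_pair[0]`` is recomputed at the low and high bound with common
    random numbers; the output is sorted by descending bar width
    |ICER_high − ICER_low|.
    """
    ref, alt = strategy_pair

    def _icer_with(p: ParameterSet) -> float:
        a = run_cohort(n, ref, p, seed=seed, horizon=horizon, keep_patients=False)
        b = run_cohort(n, alt, p, seed=seed, horizon=horizon, keep_patients=False)
        return icer(a, b)

    base_icer = _icer_with(params)
    rows = []
    for path, (low, high) in ranges.items():
        icer_low = _icer_with(params.with_path(path, low))
        icer_high = _icer_with(params.with_path(path, high))
        rows.append({
            "parameter": path, "low": low, "high": high,
            "icer_low": icer_low, "icer_high": icer_high,
            "width": abs(icer_high - icer_low),
        })
    df = pd.DataFrame(rows).sort_values("width", ascending=False).reset_index(drop=True)
    df.attrs["base_icer"] = base_icer
    return df
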