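"""First-order Monte Carlo microsimulation of the cancer–fracture state space.

Each simulated woman starts disease-free at the cohort initiation age on a
5-year course of aromatase-inhibitor (AI) therapy and is followed in 1-year
cycles to death, an age cap, or a fixed horizon. Within a cycle, events occur
in a fixed documented order:

1. strategy decision (screening, treatment start, DXA/drug costs);
2. breast-cancer transition, time-dependent via the fitted survival curves
   (clock resets on entering each cancer state); death in the distant-
   metastasis state comes from its fitted survival curve;
3. fracture events — unless bedridden, each site (hip, vertebral, other) can
   fracture at most once per cycle, drawn independently; two or more sites in
   one cycle count as a complex fracture; a hip fracture triggers a bedridden
   draw, and bedridden women sustain no further fractures;
4. death from background mortality, with the hazard multiplied by the
   hip-fracture hazard ratio after a hip fracture (and a configurable
   distant-metastasis hazard ratio, default 1 since metastatic mortality is
   carried by its fitted curve);
5. bone-density update (AI-induced loss during therapy, natural age-specific
   loss after);
6. cost/utility accrual with annual discounting (cycle 0 undiscounted).
   Death during a cycle forfeits that cycle's utility and life-year but keeps
   event costs already incurred (DXA, drug, acute fracture); recurring costs
   (post-fracture management, long-term care) accrue only if the cycle is
   survived. No half-cycle correction is applied.

Common random numbers: every random draw comes from a stream keyed by
(seed, event channel), and every channel draws one uniform per patient per
cycle regardless of state. Re-running with a different strategy therefore
reuses identical pre-decision event draws patient-by-patient, so strategies
differ only through their decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np

from .errors import InputError
from .params import ParameterSet
from .strategies import StrategySpec
from .survival import SurvivalFit, survival_at

__all__ = ["PatientState", "StrategyOutcome", "RngStreams", "run_cohort", "simulate_cycle"]

CANCER_STATES = ("disease_free", "locoregional_recurrence", "contralateral_recurrence", "distant_metastasis")
SITES = ("hip", "vertebral", "other")

# event-channel ids for common-random-number streams
_CH_BMD, _CH_ADH, _CH_LRS, _CH_CRS, _CH_LRS_DM, _CH_CRS_DM, _CH_DM_DEATH, \
    _CH_FX_HIP, _CH_FX_VERT, _CH_FX_OTHER, _CH_BEDRIDDEN, _CH_DEATH = range(12)
_CYCLE_CHANNELS = (_CH_LRS, _CH_CRS, _CH_LRS_DM, _CH_CRS_DM, _CH_DM_DEATH,
                   _CH_FX_HIP, _CH_FX_VERT, _CH_FX_OTHER, _CH_BEDRIDDEN, _CH_DEATH)


class RngStreams:
    """Per-event-channel generators derived from one seed.

    Channel c is a Philox generator seeded by SeedSequence(seed, spawn_key=(c,));
    identical (seed, channel) always reproduces the same stream.
    """

    def __init__(self, seed: int):
        self.seed = seed
        self._gens = {
            c: np.random.Generator(np.random.Philox(np.random.SeedSequence(seed, spawn_key=(c,))))
            for c in range(12)
        }

    def uniform(self, channel: int, n: int) -> np.ndarray:
        return self._gens[channel].random(n)

    def normal(self, channel: int, n: int) -> np.ndarray:
        return self._gens[channel].standard_normal(n)


@dataclass
class PatientState:
    """One simulated woman's dynamic record (scalar view used by unit tests)."""

    age: float
    cycle: int
    cancer_state: str = "disease_free"
    time_in_state: int = 0
    fracture_counts: Dict[str, int] = field(default_factory=lambda: {s: 0 for s in SITES})
    any_prior_fracture: bool = False
    bedridden: bool = False
    tscore: float = -1.0
    on_ai: bool = True
    treatment_started: bool = False
    treatment_start_cycle: int = -1
    adherent: bool = True
    screened_out_once: bool = False
    alive: bool = True
    cost: float = 0.0
    qaly: float = 0.0
    ly: float = 0.0
    events: List[str] = field(default_factory=list)


@dataclass
class StrategyOutcome:
    """Aggregated (and per-patient) results of one strategy run."""

    strategy: str
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    mean_ly: float
    survival: np.ndarray  # fraction alive at end of each cycle, survival[0]=1 at t=0
    cum_fracture_incidence: np.ndarray  # fraction with >=1 incident fracture by cycle end
    event_counts: Dict[str, int]
    patient_cost: Optional[np.ndarray] = None
    patient_qaly: Optional[np.ndarray] = None


class _Tables:
    """Dense per-age / per-cycle lookup tables derived from a ParameterSet."""

    def __init__(self, params: ParameterSet, n_cycles: int):
        p = params
        lo, hi = p.start_age, p.max_age
        ages = np.arange(lo, hi + 2)  # +1 slack for final BMD update
        self.age_lo = lo
        self.bg_q = np.array([p.background_mortality.at(a) for a in ages])
        self.hip_hr = np.array([p.hip_fracture_mortality_hr.at(a) for a in ages])
        self.u_base = np.array([p.utilities.baseline.at(a) for a in ages])
        self.nat_loss = np.array([p.bmd_loss_natural.at(a) for a in ages])
        zr = p.zscore_reference
        self.z_mean = np.array([zr.age_mean.at(a) for a in ages])
        self.z_sd = np.array([zr.age_sd.at(a) for a in ages])
        self.young_mean = zr.young_adult_mean
        self.young_sd = zr.young_adult_sd
        self.fx_rate = {
            s: np.array([p.fracture_rate_curves[s].rate_at(a) for a in ages]) for s in SITES
        }
        self.ln_g = {s: math.log(p.fracture_gradient[s]) for s in SITES}
        # per-cycle leave probabilities by time-in-state tau = 1..n_cycles
        self.leave: Dict[str, np.ndarray] = {}
        for name, spec in p.cancer_transition_fits.items():
            fit = SurvivalFit(spec.distribution, dict(spec.params))
            taus = np.arange(0, n_cycles + 1, dtype=float)
            s = np.asarray(survival_at(fit, taus))
            leave = np.zeros(n_cycles + 1)
            for tau in range(1, n_cycles + 1):
                leave[tau] = 1.0 - (s[tau] / s[tau - 1] if s[tau - 1] > 0 else 0.0)
            self.leave[name] = np.clip(leave, 0.0, 1.0)


class _Cohort:
    """Vectorized patient-state arrays."""

    def __init__(self, n: int, params: ParameterSet, streams: RngStreams,
                 tscore_override: Optional[float] = None):
        self.n = n
        base_t = params.bmd_baseline.at(params.start_age)
        z = streams.normal(_CH_BMD, n)
        self.tscore = (np.full(n, tscore_override, dtype=float) if tscore_override is not None
                       else base_t + params.bmd_baseline_sd * z)
        self.u_adherent = streams.uniform(_CH_ADH, n)
        self.cancer = np.zeros(n, dtype=np.int8)  # index into CANCER_STATES
        self.tis = np.zeros(n, dtype=np.int32)  # time in current cancer state
        self.fx_ever = {s: np.zeros(n, dtype=bool) for s in SITES}
        self.any_prior = np.full(n, params.initial_prior_fracture, dtype=bool)
        self.bedridden = np.zeros(n, dtype=bool)
        self.alive = np.ones(n, dtype=bool)
        self.treat_started = np.zeros(n, dtype=bool)
        self.treat_start = np.full(n, -1, dtype=np.int32)
        self.adherent = np.zeros(n, dtype=bool)
        self.screened_once = np.zeros(n, dtype=bool)
        self.cost = np.zeros(n)
        self.qaly = np.zeros(n)
        self.ly = np.zeros(n)
        self.incident_fx = np.zeros(n, dtype=bool)
        self.counts: Dict[str, int] = {
            "fracture_hip": 0, "fracture_vertebral": 0, "fracture_other": 0,
            "complex_fracture": 0, "bedridden": 0, "screens": 0,
            "treatment_starts": 0, "cancer_deaths": 0, "deaths": 0,
        }


def _step(c: _Cohort, t: int, strategy: StrategySpec, params: ParameterSet,
          tables: _Tables, streams: RngStreams) -> None:
    """Advance the whole cohort one cycle (cycle index t, 0-based)."""
    n = c.n
    age_idx = t  # age = start_age + t
    alive0 = c.alive.copy()
    disc = (1.0 + params.discount_rate) ** (-t)
    cycle_cost = np.zeros(n)  # event costs kept even if death occurs this cycle

    # draw all event channels up front (CRN: consumed regardless of state)
    u = {ch: streams.uniform(ch, n) for ch in _CYCLE_CHANNELS}

    # ---- 1. strategy decision ------------------------------------------
    adher_p = strategy.adherence if strategy.adherence is not None else params.adherence
    start_mask = np.zeros(n, dtype=bool)
    if strategy.treat_threshold == "universal":
        if t == 0:
            start_mask = alive0 & ~c.treat_started
    elif strategy.treat_threshold != "never":
        if strategy.screens_at(t, params.ai_duration_years):
            screen_mask = alive0 & ~c.treat_started
            if strategy.screening == "once":
                screen_mask &= ~c.screened_once
                c.screened_once |= screen_mask
            cycle_cost[screen_mask] += params.costs.dxa
            c.counts["screens"] += int(screen_mask.sum())
            start_mask = screen_mask & (c.tscore <= float(strategy.treat_threshold))
    if start_mask.any():
        c.treat_started |= start_mask
        c.treat_start[start_mask] = t
        c.adherent[start_mask] = c.u_adherent[start_mask] < adher_p
        c.counts["treatment_starts"] += int(start_mask.sum())
    if strategy.treat_threshold != "never":
        duration = strategy.duration(params)
        drug_cost = params.costs.drug_annual[strategy.drug]
        active = c.treat_started & c.adherent & (t >= c.treat_start) & (t < c.treat_start + duration)
        cycle_cost[alive0 & active] += drug_cost
        # non-adherent women fill the first prescription only
        nonadh_first = c.treat_started & ~c.adherent & (c.treat_start == t)
        cycle_cost[alive0 & nonadh_first] += drug_cost

    # ---- 2. cancer transition ------------------------------------------
    tau = np.minimum(c.tis + 1, len(tables.leave["dfs_to_lrs"]) - 1)
    died_cancer = np.zeros(n, dtype=bool)
    moved = np.zeros(n, dtype=bool)
    dfs = alive0 & (c.cancer == 0)
    to_lrs = dfs & (u[_CH_LRS] < tables.leave["dfs_to_lrs"][tau])
    to_crs = dfs & ~to_lrs & (u[_CH_CRS] < tables.leave["dfs_to_crs"][tau])
    lrs = alive0 & (c.cancer == 1)
    crs = alive0 & (c.cancer == 2)
    dm = alive0 & (c.cancer == 3)
    lrs_dm = lrs & (u[_CH_LRS_DM] < tables.leave["lrs_to_dm"][tau])
    crs_dm = crs & (u[_CH_CRS_DM] < tables.leave["crs_to_dm"][tau])
    died_cancer = dm & (u[_CH_DM_DEATH] < tables.leave["dm_to_death"][tau])
    c.cancer[to_lrs] = 1
    c.cancer[to_crs] = 2
    c.cancer[lrs_dm | crs_dm] = 3
    moved = to_lrs | to_crs | lrs_dm | crs_dm
    c.tis[alive0 & moved] = 0
    c.tis[alive0 & ~moved] += 1

    # ---- 3. fracture events --------------------------------------------
    fx_mask = alive0 & ~died_cancer & ~c.bedridden
    zscore = (tables.young_mean + tables.young_sd * c.tscore - tables.z_mean[age_idx]) / tables.z_sd[age_idx]
    events = {}
    fx_channels = {"hip": _CH_FX_HIP, "vertebral": _CH_FX_VERT, "other": _CH_FX_OTHER}
    trt_mult = _treatment_multiplier(c, t, strategy, params)
    for site in SITES:
        rate = tables.fx_rate[site][age_idx] * np.exp(-zscore * tables.ln_g[site])
        if site != "vertebral":
            rate = np.where(c.any_prior, rate * params.rr_subsequent_fracture[site], rate)
        rate = rate * trt_mult[site]
        p_site = -np.expm1(-rate)
        ev = fx_mask & (u[fx_channels[site]] < p_site)
        events[site] = ev
        cycle_cost[ev] += params.costs.fracture_acute[site]
        if params.perspective == "societal":
            cycle_cost[ev] += params.costs.indirect_post_fracture_first_year
        c.counts[f"fracture_{site}"] += int(ev.sum())
    n_sites = sum(ev.astype(int) for ev in events.values())
    c.counts["complex_fracture"] += int((n_sites >= 2).sum())
    new_bedridden = events["hip"] & (u[_CH_BEDRIDDEN] < params.p_bedridden_after_hip)
    c.counts["bedridden"] += int(new_bedridden.sum())

    # ---- 4. death -------------------------------------------------------
    q = tables.bg_q[age_idx]
    hr = np.ones(n)
    hip_now_or_ever = c.fx_ever["hip"] | events["hip"]
    hr[hip_now_or_ever] *= tables.hip_hr[age_idx]
    hr[c.cancer == 3] *= params.dm_mortality_hr
    p_death = 1.0 - (1.0 - q) ** hr
    died_bg = alive0 & ~died_cancer & (u[_CH_DEATH] < p_death)
    died = died_cancer | died_bg
    c.counts["cancer_deaths"] += int(died_cancer.sum())
    c.counts["deaths"] += int(died.sum())

    # ---- 6. accrual ------------------------------------------------------
    survived = alive0 & ~died
    c.cost += cycle_cost * disc * alive0  # event costs kept on death
    recurring = np.zeros(n)
    for site in SITES:
        recurring += np.where(c.fx_ever[site] & ~events[site], params.costs.fracture_annual[site], 0.0)
    recurring += np.where(c.bedridden, params.costs.long_term_care_annual, 0.0)
    if params.perspective == "societal":
        recurring += np.where(c.bedridden, params.costs.indirect_bedridden_annual, 0.0)
    c.cost += recurring * disc * survived

    utility = np.full(n, tables.u_base[age_idx])
    cmult = np.array([params.utilities.cancer_state[s] for s in CANCER_STATES])
    utility *= cmult[c.cancer]
    for site in SITES:
        first = params.utilities.fracture_first_year[site]
        subs = params.utilities.fracture_subsequent[site]
        utility *= np.where(events[site], first, np.where(c.fx_ever[site], subs, 1.0))
    utility = np.where(c.bedridden, params.utilities.bedridden, utility)
    c.qaly += utility * disc * survived
    c.ly += 1.0 * survived

    # ---- 5. BMD update + state roll-over --------------------------------
    on_ai = t < params.ai_duration_years
    loss = params.bmd_loss_on_ai if on_ai else tables.nat_loss[age_idx]
    c.tscore = c.tscore - loss
    for site in SITES:
        c.fx_ever[site] |= events[site]
        c.any_prior |= events[site]
        c.incident_fx |= events[site]
    c.bedridden |= new_bedridden
    c.alive &= ~died


def _treatment_multiplier(c: _Cohort, t: int, strategy: StrategySpec,
                          params: ParameterSet) -> Dict[str, np.ndarray]:
    """Per-site fracture-rate multiplier from anti-resorptive therapy."""
    mult = {s: np.ones(c.n) for s in SITES}
    if strategy.treat_threshold == "never" or strategy.drug is None:
        return mult
    duration = strategy.duration(params)
    residual = params.residual_duration_years[strategy.drug]
    eff = c.treat_started & c.adherent
    if not eff.any():
        return mult
    ys = t - c.treat_start.astype(float) - duration  # years since stopping
    for site in SITES:
        rr = params.treatment_rr[strategy.drug][site]
        on = eff & (ys <= 0)
        mult[site][on] = rr
        if residual > 0:
            decay = eff & (ys > 0) & (ys < residual)
            mult[site][decay] = rr + (1.0 - rr) * ys[decay] / residual
    return mult


def _n_cycles(params: ParameterSet, horizon: Union[str, int]) -> int:
    lifetime = params.max_age - params.start_age + 1
    if horizon == "lifetime":
        return lifetime
    return min(int(horizon), lifetime)


def run_cohort(
    n: int,
    strategy: StrategySpec,
    params: ParameterSet,
    seed: int,
    horizon: Union[str, int] = "lifetime",
    tscore_override: Optional[float] = None,
    keep_patients: bool = True,
) -> StrategyOutcome:
    """Simulate ``n`` individual trajectories under one strategy.

    Deterministic given (strategy, seed, n, params). ``horizon`` is
    ``"lifetime"`` (to the age cap) or a number of years.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    cycles = _n_cycles(params, horizon)
    tables = _Tables(params, cycles)
    streams = RngStreams(seed)
    c = _Cohort(n, params, streams, tscore_override=tscore_override)
    survival = np.ones(cycles + 1)
    cumfx = np.zeros(cycles + 1)
    for t in range(cycles):
        if not c.alive.any():
            # keep consuming streams? death of all: stop; CRN alignment across
            # strategies is preserved because draws are keyed per cycle.
            survival[t + 1 :] = 0.0
            cumfx[t + 1 :] = cumfx[t]
            break
        _step(c, t, strategy, params, tables, streams)
        survival[t + 1] = c.alive.mean()
        cumfx[t + 1] = c.incident_fx.mean()
    mean_cost = float(c.cost.mean())
    mean_qaly = float(c.qaly.mean())
    return StrategyOutcome(
        strategy=strategy.name,
        n=n,
        mean_cost=mean_cost,
        mean_qaly=mean_qaly,
        se_cost=float(c.cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(c.qaly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        mean_ly=float(c.ly.mean()),
        survival=survival,
        cum_fracture_incidence=cumfx,
        event_counts=dict(c.counts),
        patient_cost=c.cost if keep_patients else None,
        patient_qaly=c.qaly if keep_patients else None,
    )


# ---------------------------------------------------------------------------
# scalar single-patient interface (unit-test view over the same step code)
# ---------------------------------------------------------------------------


def simulate_cycle(
    patient: PatientState,
    strategy: StrategySpec,
    params: ParameterSet,
    streams: RngStreams,
) -> PatientState:
    """Advance one patient one cycle through the identical vectorized step.

    Raises :class:`InputError` if the patient is already dead.
    """
    if not patient.alive:
        raise InputError("cannot simulate a cycle for a dead patient")
    t = patient.cycle
    cycles = _n_cycles(params, "lifetime")
    tables = _Tables(params, max(cycles, t + 1))
    c = _Cohort(1, params, RngStreams(0), tscore_override=patient.tscore)
    c.cancer[0] = CANCER_STATES.index(patient.cancer_state)
    c.tis[0] = patient.time_in_state
    for s in SITES:
        c.fx_ever[s][0] = patient.fracture_counts.get(s, 0) > 0
    c.any_prior[0] = patient.any_prior_fracture
    c.bedridden[0] = patient.bedridden
    c.treat_started[0] = patient.treatment_started
    c.treat_start[0] = patient.treatment_start_cycle
    c.adherent[0] = patient.adherent
    c.screened_once[0] = patient.screened_out_once
    c.u_adherent[0] = 0.0 if patient.adherent else 1.0
    c.cost[0] = 0.0
    _step(c, t, strategy, params, tables, streams)
    new_counts = dict(patient.fracture_counts)
    for s in SITES:
        if c.fx_ever[s][0] and patient.fracture_counts.get(s, 0) == 0:
            new_counts[s] = 1
    disc = (1.0 + params.discount_rate) ** (-t)
    return PatientState(
        age=patient.age + 1,
        cycle=t + 1,
        cancer_state=CANCER_STATES[c.cancer[0]],
        time_in_state=int(c.tis[0]),
        fracture_counts=new_counts,
        any_prior_fracture=bool(c.any_prior[0]),
        bedridden=bool(c.bedridden[0]),
        tscore=float(c.tscore[0]),
        on_ai=patient.cycle + 1 <= params.ai_duration_years,
        treatment_started=bool(c.treat_started[0]),
        treatment_start_cycle=int(c.treat_start[0]),
        adherent=bool(c.adherent[0]),
        screened_out_once=bool(c.screened_once[0]),
        alive=bool(c.alive[0]),
        cost=patient.cost + float(c.cost[0]),
        qaly=patient.qaly + float(c.qaly[0]),
        ly=patient.ly + float(c.ly[0]),
        events=list(patient.events),
    )
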