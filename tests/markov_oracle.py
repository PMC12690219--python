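"""Deterministic cohort-Markov oracle for the heterogeneity-free reduction.

Independent expectation calculation used to validate the microsimulation:
with fixed bone density (no BMD drift), constant-hazard (exponential) cancer
transitions, no repeat-fracture multiplier and no bedridden state, the
individual-level model collapses to a Markov cohort over states
(cancer state × fracture-history flags). This module iterates that cohort
distribution cycle by cycle, replicating the engine's documented within-cycle
order and accounting rules, and returns exact expected discounted cost and
QALYs per patient.
"""

import math
from itertools import product

import numpy as np

SITES = ("hip", "vertebral", "other")


def reduced_params(base):
    """Heterogeneity-free reduction of a ParameterSet (pure copy)."""
    p = base.model_copy(deep=True)
    p.bmd_loss_on_ai = 0.0
    p.bmd_loss_natural = {a: 0.0 for a in range(p.start_age, p.max_age + 2)}
    p.zscore_reference.age_mean = {p.start_age: p.zscore_reference.age_mean.at(p.start_age)}
    p.zscore_reference.age_sd = {p.start_age: p.zscore_reference.age_sd.at(p.start_age)}
    p.rr_subsequent_fracture = {"hip": 1.0, "vertebral": 1.0, "other": 1.0}
    p.p_bedridden_after_hip = 0.0
    # constant-hazard cancer transitions
    rates = {"dfs_to_lrs": 0.012, "dfs_to_crs": 0.004, "lrs_to_dm": 0.08,
             "crs_to_dm": 0.06, "dm_to_death": 0.25}
    p.cancer_transition_fits = {
        k: {"distribution": "exponential", "params": {"rate": r}} for k, r in rates.items()
    }
    return p


def expected_cost_qaly(p, tscore: float, horizon_cycles: int = None):
    """Exact expected discounted (cost, qaly) for the no-intervention strategy."""
    n_cycles = (p.max_age - p.start_age + 1) if horizon_cycles is None else horizon_cycles
    leave = {}
    for name, spec in p.cancer_transition_fits.items():
        assert spec.distribution == "exponential"
        leave[name] = 1.0 - math.exp(-spec.params["rate"])
    zr = p.zscore_reference
    z = (zr.young_adult_mean + zr.young_adult_sd * tscore - zr.age_mean.at(p.start_age)) / zr.age_sd.at(p.start_age)

    # mass over (cancer 0..3, flags 0..7)
    m = np.zeros((4, 8))
    m[0, 0] = 1.0
    exp_cost = 0.0
    exp_qaly = 0.0
    cmult = [p.utilities.cancer_state[s] for s in
             ("disease_free", "locoregional_recurrence", "contralateral_recurrence", "distant_metastasis")]

    for t in range(n_cycles):
        age = p.start_age + t
        disc = (1.0 + p.discount_rate) ** (-t)
        q = p.background_mortality.at(age)
        hip_hr = p.hip_fracture_mortality_hr.at(age)
        u_base = p.utilities.baseline.at(age)
        p_site = {}
        for s in SITES:
            rate = p.fracture_rate_curves[s].rate_at(age) * p.fracture_gradient[s] ** (-z)
            p_site[s] = 1.0 - math.exp(-rate)

        new_m = np.zeros((4, 8))
        for c in range(4):
            for f in range(8):
                mass = m[c, f]
                if mass == 0:
                    continue
                # cancer transition
                p1, p2 = leave["dfs_to_lrs"], leave["dfs_to_crs"]
                if c == 0:
                    moves = {0: (1 - p1) * (1 - p2), 1: p1, 2: (1 - p1) * p2}
                elif c == 1:
                    moves = {1: 1 - leave["lrs_to_dm"], 3: leave["lrs_to_dm"]}
                elif c == 2:
                    moves = {2: 1 - leave["crs_to_dm"], 3: leave["crs_to_dm"]}
                else:
                    pdm = leave["dm_to_death"]
                    moves = {3: 1 - pdm}
                    # cancer death: no fracture step, no accrual
                for c2, pc in moves.items():
                    m2 = mass * pc
                    if m2 == 0:
                        continue
                    # fracture event subsets
                    for e in product((0, 1), repeat=3):
                        pe = 1.0
                        for i, s in enumerate(SITES):
                            pe *= p_site[s] if e[i] else 1 - p_site[s]
                        m3 = m2 * pe
                        if m3 == 0:
                            continue
                        f2 = f | sum(b << i for i, b in enumerate(e))
                        hr = (hip_hr if (f2 & 1) else 1.0) * (p.dm_mortality_hr if c2 == 3 else 1.0)
                        p_die = 1.0 - (1.0 - q) ** hr
                        # event costs accrue even on same-cycle death
                        acute = sum(p.costs.fracture_acute[s] for i, s in enumerate(SITES) if e[i])
                        exp_cost += m3 * acute * disc
                        surv = m3 * (1 - p_die)
                        recurring = sum(
                            p.costs.fracture_annual[s]
                            for i, s in enumerate(SITES)
                            if (f & (1 << i)) and not e[i]
                        )
                        exp_cost += surv * recurring * disc
                        util = u_base * cmult[c2]
                        for i, s in enumerate(SITES):
                            if e[i]:
                                util *= p.utilities.fracture_first_year[s]
                            elif f & (1 << i):
                                util *= p.utilities.fracture_subsequent[s]
                        exp_qaly += surv * util * disc
                        new_m[c2, f2] += surv
        m = new_m
    return exp_cost, exp_qaly
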