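"""Microsimulation engine: cycle mechanics, accounting identities, common
random numbers and agreement with the deterministic cohort oracle."""

import numpy as np
import pytest

from markov_oracle import expected_cost_qaly, reduced_params
from osteocea.engine import PatientState, RngStreams, run_cohort, simulate_cycle
from osteocea.errors import InputError
from osteocea.strategies import get_strategy


def _quiet_params(base):
    """No cancer transitions, no fractures, no mortality, no BMD drift."""
    p = base.model_copy(deep=True)
    p.cancer_transition_fits = {
        k: {"distribution": "exponential", "params": {"rate": 0.0}}
        for k in p.cancer_transition_fits
    }
    for site in p.fracture_rate_curves:
        p.fracture_rate_curves[site].a = 0.0
    p.background_mortality = {a: 0.0 for a in range(p.start_age, p.max_age + 2)}
    return p


class TestSimulateCycle:
    def test_null_event_cycle_changes_only_clock_bmd_accumulators(self, default_params):
        p = _quiet_params(default_params)
        patient = PatientState(age=60, cycle=0, tscore=-1.0)
        after = simulate_cycle(patient, get_strategy("no_intervention"), p, RngStreams(1))
        assert after.age == 61 and after.cycle == 1
        assert after.cancer_state == "disease_free"
        assert after.fracture_counts == patient.fracture_counts
        assert after.alive
        assert after.tscore == pytest.approx(-1.0 - p.bmd_loss_on_ai)
        assert after.qaly > 0 and after.ly == 1.0

    def test_forced_hip_fracture_leads_to_bedridden_then_no_more_fractures(self, default_params):
        p = default_params.model_copy(deep=True)
        p.p_bedridden_after_hip = 1.0
        p.fracture_rate_curves["hip"].a = 50.0  # hip fracture certain this cycle
        p.background_mortality = {a: 0.0 for a in range(p.start_age, p.max_age + 2)}
        patient = PatientState(age=60, cycle=0, tscore=-1.0)
        after = simulate_cycle(patient, get_strategy("no_intervention"), p, RngStreams(1))
        assert after.fracture_counts["hip"] == 1
        assert after.bedridden
        # bedridden: later cycles draw no fractures even at enormous rates
        later = simulate_cycle(after, get_strategy("no_intervention"), p, RngStreams(2))
        assert later.fracture_counts == after.fracture_counts

    def test_certain_background_mortality_is_absorbing(self, default_params):
        p = _quiet_params(default_params)
        p.background_mortality = {a: 1.0 for a in range(p.start_age, p.max_age + 2)}
        patient = PatientState(age=60, cycle=0, tscore=-1.0)
        after = simulate_cycle(patient, get_strategy("no_intervention"), p, RngStreams(1))
        assert not after.alive
        assert after.qaly == 0.0 and after.ly == 0.0  # death forfeits the cycle
        with pytest.raises(InputError):
            simulate_cycle(after, get_strategy("no_intervention"), p, RngStreams(1))


class TestRunCohort:
    def test_n_below_one_rejected(self, default_params):
        with pytest.raises(InputError):
            run_cohort(0, get_strategy("no_intervention"), default_params, seed=1)

    def test_qaly_accounting_identity(self, default_params):
        # horizon 10, zero discount, utility ≡ 1, no events → QALY = 10 exactly
        p = _quiet_params(default_params)
        p.discount_rate = 0.0
        p.utilities.baseline = {a: 1.0 for a in range(p.start_age, p.max_age + 2)}
        p.utilities.cancer_state = {k: 1.0 for k in p.utilities.cancer_state}
        out = run_cohort(50, get_strategy("no_intervention"), p, seed=1, horizon=10)
        assert out.mean_qaly == pytest.approx(10.0, abs=1e-12)
        assert out.mean_ly == pytest.approx(10.0, abs=1e-12)

    def test_discounting_closed_form(self, default_params):
        # same setup with 5% discounting: QALY = Σ_{t=0..9} 1.05^−t
        p = _quiet_params(default_params)
        p.utilities.baseline = {a: 1.0 for a in range(p.start_age, p.max_age + 2)}
        p.utilities.cancer_state = {k: 1.0 for k in p.utilities.cancer_state}
        out = run_cohort(20, get_strategy("no_intervention"), p, seed=1, horizon=10)
        expected = sum(1.05 ** (-t) for t in range(10))
        assert out.mean_qaly == pytest.approx(expected, abs=1e-9)

    def test_life_table_oracle_with_mortality_only(self, default_params):
        # zero fracture/cancer risk → mean LY equals Σ_t Π_{k≤t}(1−q_k)
        p = _quiet_params(default_params)
        p.background_mortality = default_params.background_mortality
        n = 50000
        out = run_cohort(n, get_strategy("no_intervention"), p, seed=9)
        cycles = p.max_age - p.start_age + 1
        surv, expect = 1.0, 0.0
        for t in range(cycles):
            surv *= 1.0 - p.background_mortality.at(p.start_age + t)
            expect += surv
        sd = np.sqrt(max(out.mean_ly, 1.0))  # per-patient LY variance bound
        assert abs(out.mean_ly - expect) < 3 * 8.0 / np.sqrt(n)  # LY sd ≈ 8 y

    def test_bit_identical_reruns(self, default_params):
        a = run_cohort(500, get_strategy("universal"), default_params, seed=11, horizon=15)
        b = run_cohort(500, get_strategy("universal"), default_params, seed=11, horizon=15)
        assert a.mean_cost == b.mean_cost and a.mean_qaly == b.mean_qaly
        np.testing.assert_array_equal(a.patient_cost, b.patient_cost)

    def test_monotone_survival_and_incidence_curves(self, default_params):
        out = run_cohort(2000, get_strategy("no_intervention"), default_params, seed=4)
        assert np.all(np.diff(out.survival) <= 0)
        assert np.all(np.diff(out.cum_fracture_incidence) >= 0)
        assert out.survival[0] == 1.0

    def test_discounted_qaly_below_horizon(self, default_params):
        out = run_cohort(1000, get_strategy("no_intervention"), default_params, seed=4, horizon=10)
        assert out.mean_qaly <= 10.0
        assert np.all(out.patient_qaly <= 10.0)


class TestCommonRandomNumbers:
    def test_neutralized_treatment_reproduces_no_intervention_exactly(self, default_params):
        """With RR ≡ 1, zero drug/DXA cost and full adherence, the universal
        strategy must give bit-identical per-patient trajectories to no
        intervention: pre-decision event draws are shared."""
        p = default_params.model_copy(deep=True)
        for drug in p.treatment_rr:
            for site in p.treatment_rr[drug]:
                p.treatment_rr[drug][site] = 1.0
        for drug in p.costs.drug_annual:
            p.costs.drug_annual[drug] = 0.0
        p.costs.dxa = 0.0
        p.adherence = 1.0
        a = run_cohort(3000, get_strategy("no_intervention"), p, seed=21)
        b = run_cohort(3000, get_strategy("universal"), p, seed=21)
        np.testing.assert_array_equal(a.patient_qaly, b.patient_qaly)
        np.testing.assert_array_equal(a.patient_cost, b.patient_cost)

    def test_strategies_share_fracture_draws_before_treatment(self, default_params):
        # first-cycle fracture counts are identical across strategies that have
        # made no treatment decision yet at cycle 0 draw time
        a = run_cohort(5000, get_strategy("no_intervention"), default_params, seed=33, horizon=1)
        b = run_cohort(5000, get_strategy("once_osteoporosis"), default_params, seed=33, horizon=1)
        # treated patients can only lower rates; untreated majority identical
        assert abs(a.event_counts["fracture_other"] - b.event_counts["fracture_other"]) <= 5


class TestMarkovOracleEquivalence:
    def test_microsimulation_matches_cohort_markov_expectation(self, default_params):
        p = reduced_params(default_params)
        tscore = -1.5
        exp_cost, exp_qaly = expected_cost_qaly(p, tscore)
        n = 50000
        out = run_cohort(n, get_strategy("no_intervention"), p, seed=17, tscore_override=tscore)
        assert abs(out.mean_cost - exp_cost) < 3 * out.se_cost
        assert abs(out.mean_qaly - exp_qaly) < 3 * out.se_qaly
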