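"""KM reconstruction, parametric fitting, AIC selection and cycle probabilities."""

import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from scipy import integrate

from osteocea.errors import FittingError, InputError
from osteocea.survival import (
    DISTRIBUTIONS,
    KMCurve,
    PseudoIPD,
    SurvivalFit,
    fit_all,
    fit_parametric,
    reconstruct_ipd,
    select_best,
    staying_probability,
    survival_at,
    transition_probability,
)
from osteocea.synthetic import make_km

EXAMPLE_FITS = {
    "exponential": SurvivalFit("exponential", {"rate": 0.15}),
    "weibull": SurvivalFit("weibull", {"scale": 6.0, "shape": 1.4}),
    "gompertz": SurvivalFit("gompertz", {"rate": 0.05, "shape": 0.15}),
    "loglogistic": SurvivalFit("loglogistic", {"scale": 5.0, "shape": 2.2}),
    "lognormal": SurvivalFit("lognormal", {"mu": 1.6, "sigma": 0.6}),
    "generalized_gamma": SurvivalFit("generalized_gamma", {"mu": 1.6, "sigma": 0.55, "q": 1.5}),
}


class TestSurvivalAt:
    def test_lognormal_median_at_exp_mu(self):
        # ln t = mu makes the standard-normal argument zero
        assert survival_at(SurvivalFit("lognormal", {"mu": 0.0, "sigma": 1.0}), 1.0) == pytest.approx(0.5)
        assert survival_at(SurvivalFit("lognormal", {"mu": 1.0, "sigma": 0.5}), math.e) == pytest.approx(0.5)

    @pytest.mark.parametrize("name", DISTRIBUTIONS)
    def test_starts_at_one_and_is_monotone(self, name):
        fit = EXAMPLE_FITS[name]
        assert survival_at(fit, 0.0) == pytest.approx(1.0)
        ts = np.linspace(0.0, 30.0, 200)
        s = survival_at(fit, ts)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            survival_at(EXAMPLE_FITS["exponential"], -1.0)

    def test_generalized_gamma_q1_matches_weibull(self):
        mu, sigma = 1.2, 0.5
        gg = SurvivalFit("generalized_gamma", {"mu": mu, "sigma": sigma, "q": 1.0})
        wb = SurvivalFit("weibull", {"scale": math.exp(mu), "shape": 1.0 / sigma})
        ts = np.linspace(0.01, 20.0, 50)
        np.testing.assert_allclose(survival_at(gg, ts), survival_at(wb, ts), atol=1e-9)

    def test_generalized_gamma_q0_matches_lognormal(self):
        gg = SurvivalFit("generalized_gamma", {"mu": 1.0, "sigma": 0.4, "q": 0.0})
        ln = SurvivalFit("lognormal", {"mu": 1.0, "sigma": 0.4})
        ts = np.linspace(0.01, 20.0, 50)
        np.testing.assert_allclose(survival_at(gg, ts), survival_at(ln, ts), atol=1e-9)

    @pytest.mark.parametrize("name", ["weibull", "gompertz", "loglogistic"])
    def test_matches_numeric_hazard_integration(self, name):
        # S(t) = exp(-∫₀ᵗ h(u) du) with h = -d ln S/du evaluated numerically
        fit = EXAMPLE_FITS[name]

        def hazard(u):
            eps = 1e-7
            return -(math.log(survival_at(fit, u + eps)) - math.log(survival_at(fit, u - eps))) / (2 * eps)

        for t in (0.5, 2.0, 5.0):
            cumh, _ = integrate.quad(hazard, 1e-6, t, limit=200)
            assert survival_at(fit, t) == pytest.approx(math.exp(-cumh), abs=1e-6)


class TestTransitionProbability:
    def test_exponential_constant_hazard_closed_form(self):
        fit = SurvivalFit("exponential", {"rate": 0.1})
        expected = 1.0 - math.exp(-0.1)
        for cycle in (1, 2, 7, 30):
            assert transition_probability(fit, cycle) == pytest.approx(expected, abs=1e-12)

    def test_flat_survival_gives_zero(self):
        fit = SurvivalFit("exponential", {"rate": 0.0})
        assert transition_probability(fit, 3) == 0.0

    def test_lognormal_first_cycle(self):
        fit = SurvivalFit("lognormal", {"mu": 0.0, "sigma": 1.0})
        assert transition_probability(fit, 1) == pytest.approx(0.5)

    def test_stay_and_leave_are_complements(self):
        fit = EXAMPLE_FITS["weibull"]
        for cycle in (1, 4, 9):
            assert staying_probability(fit, cycle) + transition_probability(fit, cycle) == pytest.approx(1.0)

    def test_cycle_zero_rejected(self):
        with pytest.raises(InputError):
            transition_probability(EXAMPLE_FITS["exponential"], 0)


class TestReconstructIpd:
    def test_two_point_curve_exhaustive(self):
        km = KMCurve(times=[0.0, 1.0], survival=[1.0, 0.5], risk_table=[(0.0, 10), (1.0, 5)])
        ipd = reconstruct_ipd(km)
        assert ipd.n == 10
        assert ipd.n_events == 5
        assert np.all(ipd.times[ipd.events == 1] == 1.0)

    def test_flat_curve_all_censored(self):
        km = KMCurve(
            times=np.linspace(0, 5, 21), survival=np.ones(21), risk_table=[(0.0, 50), (2.5, 50)]
        )
        ipd = reconstruct_ipd(km)
        assert ipd.n_events == 0
        assert ipd.n == 50

    def test_increasing_risk_table_rejected(self):
        with pytest.raises(InputError):
            KMCurve(times=[0.0, 1.0], survival=[1.0, 0.9], risk_table=[(0.0, 10), (1.0, 12)])

    def test_exponential_digitize_reconstruct_matches_km(self):
        km, _ = make_km("exponential", {"rate": 0.1}, n=500, censor_time=5.0, grid=0.25, seed=3)
        ipd = reconstruct_ipd(km)
        kmf = KaplanMeierFitter().fit(np.clip(ipd.times, 1e-9, None), event_observed=ipd.events)
        recon = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.max(np.abs(recon - km.survival)) < 0.02

    @pytest.mark.parametrize("name", DISTRIBUTIONS)
    def test_reconstruction_postcondition_all_families(self, name):
        km, _ = make_km(name, EXAMPLE_FITS[name].params, n=400, censor_time=10.0, grid=0.25, seed=5)
        ipd = reconstruct_ipd(km)
        kmf = KaplanMeierFitter().fit(np.clip(ipd.times, 1e-9, None), event_observed=ipd.events)
        recon = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.max(np.abs(recon - km.survival)) < 0.02


class TestFitParametric:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(42)
        times = np.exp(1.0 + 0.5 * rng.standard_normal(2000))
        ipd = PseudoIPD(times, np.ones(2000, dtype=int))
        fit = fit_parametric(ipd, "lognormal")
        assert abs(fit.params["mu"] - 1.0) < 0.05
        assert abs(fit.params["sigma"] - 0.5) < 0.05
        exp_fit = fit_parametric(ipd, "exponential")
        assert fit.aic < exp_fit.aic

    def test_gompertz_parameter_recovery(self):
        from osteocea.synthetic import _sample_times

        rng = np.random.default_rng(9)
        times = _sample_times("gompertz", {"rate": 0.05, "shape": 0.15}, 4000, rng)
        ipd = PseudoIPD(times, np.ones(4000, dtype=int))
        fit = fit_parametric(ipd, "gompertz")
        assert fit.params["rate"] == pytest.approx(0.05, rel=0.15)
        assert fit.params["shape"] == pytest.approx(0.15, rel=0.15)

    def test_all_censored_raises(self):
        ipd = PseudoIPD(np.linspace(1, 5, 20), np.zeros(20, dtype=int))
        with pytest.raises(FittingError):
            fit_parametric(ipd, "lognormal")

    def test_too_few_records_raises(self):
        ipd = PseudoIPD([1.0, 2.0], [1, 1])
        with pytest.raises(FittingError):
            fit_parametric(ipd, "weibull")


class TestSelectBest:
    def test_minimum_aic_wins(self):
        fits = [SurvivalFit("weibull", {"scale": 1, "shape": 1}, aic=100.0),
                SurvivalFit("lognormal", {"mu": 0, "sigma": 1}, aic=98.0)]
        assert select_best(fits).distribution == "lognormal"

    def test_tie_broken_by_fewer_parameters(self):
        fits = [SurvivalFit("weibull", {"scale": 1, "shape": 1}, aic=100.0),
                SurvivalFit("exponential", {"rate": 1.0}, aic=100.0)]
        assert select_best(fits).distribution == "exponential"

    def test_singleton(self):
        fit = SurvivalFit("exponential", {"rate": 1.0}, aic=5.0)
        assert select_best([fit]) is fit

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            select_best([])


def test_pipeline_recovers_generating_family_in_most_cases():
    """Simulate → digitize → reconstruct → fit all six → select: the
    generating family must win in at least 4 of 6 cases at n = 2000."""
    hits = 0
    for name, fit in EXAMPLE_FITS.items():
        km, _ = make_km(name, fit.params, n=2000, censor_time=12.0, grid=0.1, seed=11)
        best = select_best(fit_all(reconstruct_ipd(km)))
        hits += best.distribution == name
    assert hits >= 4
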