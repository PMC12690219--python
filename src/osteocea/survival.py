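"""Parametric survival machinery for time-dependent cancer transitions.

Workflow: digitized Kaplan–Meier coordinates plus a numbers-at-risk table are
turned into pseudo individual-patient data (:func:`reconstruct_ipd`, a
Guyot-style interval allocation); six candidate parametric families are fit by
maximum likelihood (:func:`fit_parametric`); the minimum-AIC fit is selected
(:func:`select_best`); and per-cycle transition probabilities are derived from
the fitted survival function.

A fitted log-normal survival function is S(t) = 1 − Φ((ln t − μ)/σ). The
per-cycle probability of *staying* in the state is S(t)/S(t−1); the engine
consumes the complement, 1 − S(t)/S(t−1), the probability of leaving during
cycle t. Both are exposed.

Generalized gamma uses the (μ, σ, Q) parameterization: ln T = μ + σ·W with
exp(Q·W)/Q² ~ Gamma(1/Q², 1). Q = 1 recovers a Weibull member (shape 1/σ,
scale e^μ) and Q → 0 the log-normal(μ, σ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from .errors import ConvergenceError, FittingError, InputError

__all__ = [
    "KMCurve",
    "PseudoIPD",
    "SurvivalFit",
    "DISTRIBUTIONS",
    "reconstruct_ipd",
    "fit_parametric",
    "fit_all",
    "select_best",
    "survival_at",
    "staying_probability",
    "transition_probability",
]

DISTRIBUTIONS = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "generalized_gamma",
)

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "generalized_gamma": 3,
}


@dataclass
class KMCurve:
    """Digitized Kaplan–Meier curve with its numbers-at-risk table."""

    times: np.ndarray  # years, monotone non-decreasing
    survival: np.ndarray  # non-increasing, starts at 1
    risk_table: List[Tuple[float, int]]  # (time, number at risk)
    total_events: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise InputError("times and survival must have equal length")
        if np.any(self.times < 0):
            raise InputError("KM times must be non-negative")
        if np.any(np.diff(self.times) < 0):
            raise InputError("KM times must be non-decreasing")
        if self.survival[0] > 1 + 1e-12:
            raise InputError("survival must start at or below 1")
        if np.any(np.diff(self.survival) > 1e-12):
            raise InputError("survival must be non-increasing")
        if np.any(self.survival < -1e-12) :
            raise InputError("survival must be non-negative")
        at_risk = [n for _, n in self.risk_table]
        if any(n2 > n1 for n1, n2 in zip(at_risk, at_risk[1:])):
            raise InputError("numbers at risk must be non-increasing")


@dataclass
class PseudoIPD:
    """Reconstructed pseudo individual-patient data."""

    times: np.ndarray  # event or censoring time, years
    events: np.ndarray  # 1 = event, 0 = censored

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise InputError("times and events must have equal length")
        if np.any(self.times < 0):
            raise InputError("IPD times must be non-negative")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class SurvivalFit:
    """A fitted parametric survival distribution.

    ``params`` keys by family: exponential ``rate``; weibull ``scale``,
    ``shape``; gompertz ``rate`` (baseline hazard a), ``shape`` (log-hazard
    slope b, any sign); loglogistic ``scale``, ``shape``; lognormal ``mu``,
    ``sigma``; generalized_gamma ``mu``, ``sigma``, ``q``.
    """

    distribution: str
    params: Dict[str, float]
    aic: float = math.nan
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise InputError(f"unknown distribution '{self.distribution}'")
        sigma = self.params.get("sigma")
        if sigma is not None and sigma <= 0:
            raise InputError("sigma must be > 0")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.distribution]


# ---------------------------------------------------------------------------
# survival functions
# ---------------------------------------------------------------------------


def _sf(fit: SurvivalFit, t: np.ndarray) -> np.ndarray:
    p = fit.params
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        if fit.distribution == "exponential":
            return np.exp(-p["rate"] * t)
        if fit.distribution == "weibull":
            return np.exp(-np.power(t / p["scale"], p["shape"]))
        if fit.distribution == "gompertz":
            a, b = p["rate"], p["shape"]
            if abs(b) < 1e-12:
                return np.exp(-a * t)
            return np.exp(-a / b * (np.expm1(b * t)))
        if fit.distribution == "loglogistic":
            return 1.0 / (1.0 + np.power(t / p["scale"], p["shape"]))
        if fit.distribution == "lognormal":
            out = np.ones_like(t)
            pos = t > 0
            out[pos] = stats.norm.sf((np.log(t[pos]) - p["mu"]) / p["sigma"])
            return out
        if fit.distribution == "generalized_gamma":
            return _gengamma_sf(t, p["mu"], p["sigma"], p["q"])
    raise InputError(fit.distribution)


def _gengamma_scipy(mu: float, sigma: float, q: float):
    a = 1.0 / q**2
    c = q / sigma
    scale = math.exp(mu) * (q**2) ** (sigma / q)
    return stats.gengamma(a, c, scale=scale)


def _gengamma_sf(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    if abs(q) < 1e-8:
        out = np.ones_like(t)
        pos = t > 0
        out[pos] = stats.norm.sf((np.log(t[pos]) - mu) / sigma)
        return out
    return _gengamma_scipy(mu, sigma, q).sf(t)


def survival_at(fit: SurvivalFit, t: float | np.ndarray) -> float | np.ndarray:
    """S(t) of the fitted distribution; S(0) = 1, non-increasing, in [0, 1]."""
    scalar = np.isscalar(t)
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0):
        raise InputError("t must be >= 0")
    out = np.clip(_sf(fit, arr), 0.0, 1.0)
    return float(out[0]) if scalar else out


def staying_probability(fit: SurvivalFit, cycle: int) -> float:
    """S(t)/S(t−1): probability of remaining in the state through cycle t."""
    if cycle < 1:
        raise InputError("cycle must be >= 1")
    s_prev = survival_at(fit, float(cycle - 1))
    if s_prev <= 0:
        raise InputError(f"S({cycle - 1}) = 0: state already absorbed")
    return min(1.0, float(survival_at(fit, float(cycle)) / s_prev))


def transition_probability(fit: SurvivalFit, cycle: int) -> float:
    """Per-cycle probability of leaving the state: 1 − S(t)/S(t−1)."""
    return 1.0 - staying_probability(fit, cycle)


# ---------------------------------------------------------------------------
# Guyot-style IPD reconstruction
# ---------------------------------------------------------------------------


def reconstruct_ipd(km: KMCurve) -> PseudoIPD:
    """Allocate events and censorings consistent with the risk table.

    Within each risk-table interval, the number of censorings is iterated
    until the implied number at risk at the start of the next interval matches
    the published count; censoring times are spread uniformly over the
    interval, and events at each digitized time follow from the KM product
    relation. Patients still at risk after the last digitized time are
    administratively censored there.
    """
    if len(km.risk_table) < 2:
        raise InputError("risk table needs at least 2 entries")

    t = km.times
    s = km.survival
    K = t.size
    trisk = [rt for rt, _ in km.risk_table]
    nrisk = [n for _, n in km.risk_table]
    J = len(trisk)

    # digitized indices belonging to each risk interval
    lower = []
    for j in range(J):
        lower.append(int(np.searchsorted(t, trisk[j], side="left")))
    upper = [lower[j + 1] - 1 for j in range(J - 1)] + [K - 1]

    d = np.zeros(K, dtype=int)  # events at each digitized time
    c_times: List[float] = []  # censoring times
    n_hat = np.zeros(K + 1, dtype=float)
    n_hat[lower[0]] = nrisk[0]

    km_prev = 1.0  # KM estimate at last event time processed

    def run_interval(j: int, ncen: int, n_start: float, km_start: float):
        """Process interval j with ncen censorings; return state at its end."""
        first, last = lower[j], upper[j]
        t_lo = trisk[j]
        t_hi = trisk[j + 1] if j < J - 1 else t[last]
        if ncen > 0 and t_hi > t_lo:
            cts = t_lo + (np.arange(1, ncen + 1) - 0.5) / ncen * (t_hi - t_lo)
        else:
            cts = np.array([])
        dj = np.zeros(last - first + 1, dtype=int)
        cj = np.zeros(last - first + 1, dtype=int)
        for k in range(first, last + 1):
            hi = t[k + 1] if k < K - 1 else np.inf
            cj[k - first] = int(np.sum((cts >= t[k]) & (cts < hi)))
        n_k = n_start
        km_e = km_start
        for k in range(first, last + 1):
            if km_e > 0 and n_k > 0:
                dk = int(round(n_k * (1.0 - s[k] / km_e)))
                dk = max(0, min(dk, int(n_k)))
            else:
                dk = 0
            if dk > 0:
                km_e = km_e * (1.0 - dk / n_k)
            dj[k - first] = dk
            n_k = n_k - dk - cj[k - first]
            if n_k < 0:
                n_k = 0
        return dj, cj, cts, n_k, km_e

    n_start = float(nrisk[0])
    for j in range(J):
        if j < J - 1:
            # iterate the censor count until the implied number at risk at the
            # start of the next interval — after the events allocated at its
            # first digitized time — matches the published count
            def peek_diff(n_end: float, km_e: float) -> int:
                k_next = lower[j + 1]
                if km_e > 0 and n_end > 0:
                    d_peek = int(round(n_end * (1.0 - s[k_next] / km_e)))
                    d_peek = max(0, min(d_peek, int(n_end)))
                else:
                    d_peek = 0
                return int(round(n_end - d_peek - nrisk[j + 1]))

            ncen = max(0, int(round(n_start * (s[lower[j + 1]] / max(s[lower[j]], 1e-12)))) - nrisk[j + 1])
            best = None
            for _ in range(60):
                dj, cj, cts, n_end, km_e = run_interval(j, ncen, n_start, km_prev)
                diff = peek_diff(n_end, km_e)
                if best is None or abs(diff) < abs(best[0]):
                    best = (diff, dj, cj, cts, n_end, km_e, ncen)
                if diff == 0:
                    break
                ncen = ncen + diff
                if ncen < 0:
                    ncen = 0
                    dj, cj, cts, n_end, km_e = run_interval(j, ncen, n_start, km_prev)
                    diff = peek_diff(n_end, km_e)
                    if abs(diff) < abs(best[0]):
                        best = (diff, dj, cj, cts, n_end, km_e, ncen)
                    break
            _, dj, cj, cts, n_end, km_e, _ = best
        else:
            dj, cj, cts, n_end, km_e = run_interval(j, 0, n_start, km_prev)
        first, last = lower[j], upper[j]
        d[first : last + 1] += dj
        c_times.extend(cts.tolist())
        n_start = n_end
        km_prev = km_e

    # administrative censoring of everyone still at risk at the final time
    remaining = int(round(n_start))
    times: List[float] = []
    events: List[int] = []
    for k in range(K):
        times.extend([float(t[k])] * d[k])
        events.extend([1] * d[k])
    times.extend(c_times)
    events.extend([0] * len(c_times))
    times.extend([float(t[-1])] * max(0, remaining))
    events.extend([0] * max(0, remaining))
    order = np.argsort(times, kind="stable")
    return PseudoIPD(np.asarray(times)[order], np.asarray(events)[order])


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


def fit_parametric(ipd: PseudoIPD, distribution: str) -> SurvivalFit:
    """Fit one parametric family to pseudo-IPD by maximum likelihood.

    AIC = 2k − 2·loglik. Requires ≥ 10 records and ≥ 1 event.
    """
    if distribution not in DISTRIBUTIONS:
        raise InputError(f"unknown distribution '{distribution}'")
    if ipd.n < 10:
        raise FittingError(f"need >= 10 records, got {ipd.n}")
    if ipd.n_events < 1:
        raise FittingError("no events: parametric fit is unidentifiable")

    durations = np.clip(ipd.times, 1e-8, None)
    events = ipd.events.astype(bool)

    if distribution == "gompertz":
        return _fit_gompertz(durations, events)

    import lifelines

    fitters = {
        "exponential": lifelines.ExponentialFitter,
        "weibull": lifelines.WeibullFitter,
        "loglogistic": lifelines.LogLogisticFitter,
        "lognormal": lifelines.LogNormalFitter,
        "generalized_gamma": lifelines.GeneralizedGammaFitter,
    }
    fitter = fitters[distribution]()
    try:
        fitter.fit(durations, event_observed=events)
    except Exception as exc:
        raise ConvergenceError(f"{distribution} fit failed: {exc}") from exc

    if distribution == "exponential":
        params = {"rate": 1.0 / float(fitter.lambda_)}
    elif distribution == "weibull":
        params = {"scale": float(fitter.lambda_), "shape": float(fitter.rho_)}
    elif distribution == "loglogistic":
        params = {"scale": float(fitter.alpha_), "shape": float(fitter.beta_)}
    elif distribution == "lognormal":
        params = {"mu": float(fitter.mu_), "sigma": float(fitter.sigma_)}
    else:  # generalized_gamma: lifelines uses (mu, ln sigma, lambda=Q)
        params = {
            "mu": float(fitter.mu_),
            "sigma": float(np.exp(fitter.ln_sigma_)),
            "q": float(fitter.lambda_),
        }
    loglik = float(fitter.log_likelihood_)
    k = _N_PARAMS[distribution]
    fit = SurvivalFit(distribution, params, aic=2.0 * k - 2.0 * loglik, n_fit=ipd.n)
    if not np.isfinite(fit.aic):
        raise ConvergenceError(f"{distribution} fit produced non-finite AIC")
    return fit


def _fit_gompertz(durations: np.ndarray, events: np.ndarray) -> SurvivalFit:
    """MLE for the Gompertz hazard h(t) = a·exp(b·t), b unrestricted."""

    d = events.astype(float)

    def nll(theta: np.ndarray) -> float:
        ln_a, b = theta
        a = math.exp(ln_a)
        if abs(b) < 1e-10:
            cumh = a * durations
        else:
            cumh = a / b * np.expm1(b * durations)
        ll = np.sum(d * (ln_a + b * durations)) - np.sum(cumh)
        return -ll

    best = None
    for b0 in (0.05, -0.05, 0.3):
        res = optimize.minimize(
            nll,
            x0=np.array([math.log(max(events.mean() / durations.mean(), 1e-6)), b0]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("gompertz fit failed")
    ln_a, b = best.x
    loglik = -float(best.fun)
    return SurvivalFit(
        "gompertz",
        {"rate": math.exp(ln_a), "shape": float(b)},
        aic=2.0 * 2 - 2.0 * loglik,
        n_fit=int(durations.size),
    )


def fit_all(ipd: PseudoIPD, distributions: Sequence[str] = DISTRIBUTIONS) -> List[SurvivalFit]:
    """Fit every requested family, silently skipping non-convergent ones."""
    fits = []
    for name in distributions:
        try:
            fits.append(fit_parametric(ipd, name))
        except ConvergenceError:
            continue
    if not fits:
        raise FittingError("no distribution converged")
    return fits


def select_best(fits: Sequence[SurvivalFit]) -> SurvivalFit:
    """Minimum-AIC fit; ties broken by fewer parameters, then name order."""
    if not fits:
        raise InputError("empty fit list")
    order = {name: i for i, name in enumerate(DISTRIBUTIONS)}
    return min(fits, key=lambda f: (f.aic, f.n_params, order[f.distribution]))
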