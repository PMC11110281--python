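"""Parametric survival machinery for extrapolation beyond trial follow-up.

Implements the six families standard in health-technology-assessment
survival extrapolation (exponential, Weibull, Gompertz, log-logistic,
log-normal, generalised gamma), maximum-likelihood fitting under right
censoring with observed-information standard errors, AIC/BIC model
selection, hybrid Kaplan–Meier-plus-parametric-tail curves, and the
discounted restricted person-time integrals the partitioned survival model
consumes.

Time is measured in **months** throughout the curve layer (matching the
scale on which the log-normal meanlog/sdlog inputs are quoted: exp(meanlog)
is the median survival in months); conversion to years happens only in the
discounted integrals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "SurvivalCurve",
    "ParametricCurve",
    "StepCurve",
    "HybridCurve",
    "FittedModel",
    "FitError",
    "survival_probability",
    "fit_parametric",
    "fit_all_families",
    "select_best",
    "build_hybrid_curve",
    "discounted_state_time",
]

FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gengamma",
)

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gengamma": 3,
}


class FitError(RuntimeError):
    """Maximum-likelihood fitting failed (no events, or no convergence)."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival distribution for one endpoint of one arm.

    Parameter orders (time unit: months):

    - ``exponential``: (rate,)
    - ``weibull``: (shape, scale), S(t) = exp(-(t/scale)^shape)
    - ``gompertz``: (shape a, rate b), S(t) = exp(-(b/a)(e^{at} - 1));
      a < 0 gives a plateau at exp(b/a) (improper survival mass, permitted
      for finite-horizon extrapolation)
    - ``loglogistic``: (shape, scale), S(t) = 1 / (1 + (t/scale)^shape)
    - ``lognormal``: (meanlog, sdlog), S(t) = 1 - Phi((ln t - meanlog)/sdlog)
    - ``gengamma``: (mu, sigma, Q), the parameterisation standard in
      survival-extrapolation practice; Q -> 0 recovers the log-normal
    """

    family: str
    params: tuple[float, ...]
    param_se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(x) for x in self.params))
        if len(self.params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        p = self.params
        # indices of parameters that must be strictly positive; gompertz and
        # gengamma shapes may be negative or zero
        positive_idx = {
            "exponential": (0,),
            "weibull": (0, 1),
            "gompertz": (1,),
            "loglogistic": (0, 1),
            "lognormal": (1,),
            "gengamma": (1,),
        }[self.family]
        if not all(p[i] > 0 for i in positive_idx):
            raise ValueError(f"{self.family} parameters violate positivity: {p}")

    # -- survival / density -------------------------------------------------

    def log_survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be non-negative")
        p = self.params
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if self.family == "exponential":
                out = -p[0] * t
            elif self.family == "weibull":
                out = -((t / p[1]) ** p[0])
            elif self.family == "gompertz":
                a, b = p
                if abs(a) < 1e-12:
                    out = -b * t
                else:
                    out = -(b / a) * np.expm1(a * t)
            elif self.family == "loglogistic":
                out = -np.log1p((t / p[1]) ** p[0])
            elif self.family == "lognormal":
                out = np.where(
                    t > 0,
                    stats.norm.logsf((np.log(np.where(t > 0, t, 1.0)) - p[0]) / p[1]),
                    0.0,
                )
            else:  # gengamma
                out = np.log(np.maximum(_gengamma_sf(t, *p), 1e-300))
        return np.where(t == 0, 0.0, out)

    def survival(self, t) -> np.ndarray:
        return np.exp(self.log_survival(t))

    def log_density(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("density requires strictly positive times")
        p = self.params
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if self.family == "exponential":
                return np.log(p[0]) - p[0] * t
            if self.family == "weibull":
                z = t / p[1]
                return np.log(p[0] / p[1]) + (p[0] - 1) * np.log(z) - z ** p[0]
            if self.family == "gompertz":
                a, b = p
                if abs(a) < 1e-12:
                    return np.log(b) - b * t
                return np.log(b) + a * t - (b / a) * np.expm1(a * t)
            if self.family == "loglogistic":
                sh, sc = p
                z = (t / sc) ** sh
                return np.log(sh / sc) + (sh - 1) * np.log(t / sc) - 2 * np.log1p(z)
            if self.family == "lognormal":
                z = (np.log(t) - p[0]) / p[1]
                return stats.norm.logpdf(z) - np.log(p[1] * t)
            return _gengamma_logpdf(t, *p)


def _gengamma_sf(t, mu, sigma, q):
    """Survival function of the (mu, sigma, Q) generalised gamma."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    w = (np.log(t[pos]) - mu) / sigma
    if abs(q) < 1e-8:
        out[pos] = stats.norm.sf(w)
        return out
    gam = q ** -2
    u = gam * np.exp(np.clip(q * w, -700, 700))
    out[pos] = special.gammaincc(gam, u) if q > 0 else special.gammainc(gam, u)
    return out


def _gengamma_logpdf(t, mu, sigma, q):
    t = np.asarray(t, dtype=float)
    w = (np.log(t) - mu) / sigma
    if abs(q) < 1e-8:
        return stats.norm.logpdf(w) - np.log(sigma * t)
    gam = q ** -2
    qw = np.clip(q * w, -700, 700)
    return (
        np.log(abs(q))
        + gam * np.log(gam)
        - special.gammaln(gam)
        - np.log(sigma * t)
        + gam * (qw - np.exp(qw))
    )


def survival_probability(dist: ParametricSurvival, t) -> np.ndarray | float:
    """S(t) under ``dist``; ``t`` in months, scalar or array."""
    s = dist.survival(t)
    return float(s) if np.isscalar(t) or np.ndim(t) == 0 else s


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


class SurvivalCurve:
    """A survival function S(t) on t >= 0 months.

    Subclasses implement ``__call__`` (vectorised) and carry a ``provenance``
    tag: ``parametric``, ``kaplan-meier`` or ``hybrid``.
    """

    provenance = "abstract"

    def __call__(self, t):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ParametricCurve(SurvivalCurve):
    dist: ParametricSurvival
    provenance: str = field(default="parametric", init=False)

    def __call__(self, t):
        return self.dist.survival(t)


@dataclass(frozen=True)
class StepCurve(SurvivalCurve):
    """Right-continuous step function, e.g. a Kaplan–Meier estimate.

    ``times`` are the step locations (months, increasing) and ``probs`` the
    value from each time onward; S(t) = 1 before the first step.
    """

    times: tuple[float, ...]
    probs: tuple[float, ...]
    provenance: str = field(default="kaplan-meier", init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.probs, float)
        if t.size != p.size or t.size == 0:
            raise ValueError("times and probs must be non-empty, equal length")
        if np.any(np.diff(t) < 0) or np.any(np.diff(p) > 1e-12):
            raise ValueError("step curve must have increasing times, non-increasing S")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        out = np.where(idx >= 0, np.asarray(self.probs)[np.maximum(idx, 0)], 1.0)
        return out

    @property
    def support_end(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class HybridCurve(SurvivalCurve):
    """KM curve within follow-up, rescaled parametric tail beyond.

    For t <= cutoff, S(t) = KM(t); beyond, the parametric tail is rescaled
    to join continuously: S(t) = KM(cutoff) * S_p(t) / S_p(cutoff).
    """

    km: SurvivalCurve
    dist: ParametricSurvival
    cutoff: float
    provenance: str = field(default="hybrid", init=False)

    def __post_init__(self) -> None:
        sp_cut = float(self.dist.survival(self.cutoff))
        if sp_cut <= 0.0:
            raise ValueError("parametric survival vanishes at the cutoff; tail degenerate")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        km_cut = float(np.asarray(self.km(self.cutoff)))
        sp_cut = float(self.dist.survival(self.cutoff))
        tail = km_cut * self.dist.survival(t) / sp_cut
        return np.where(t <= self.cutoff, self.km(t), tail)


def build_hybrid_curve(
    km: SurvivalCurve, dist: ParametricSurvival, cutoff: float
) -> HybridCurve:
    """Join a trial-period KM curve to a rescaled parametric extrapolation."""
    return HybridCurve(km=km, dist=dist, cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FittedModel:
    dist: ParametricSurvival
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int

    @property
    def family(self) -> str:
        return self.dist.family


def _neg_loglik(dist: ParametricSurvival, time, event) -> float:
    ll = np.sum(dist.log_density(time[event])) + np.sum(
        dist.log_survival(time[~event])
    )
    return -ll if np.isfinite(ll) else np.inf


# optimisation runs on an unconstrained scale; positive parameters are logged
_FREE = {
    "exponential": (False,),
    "weibull": (False, False),
    "gompertz": (True, False),
    "loglogistic": (False, False),
    "lognormal": (True, False),
    "gengamma": (True, False, True),
}


def _to_natural(family, theta):
    return tuple(
        t if free else math.exp(min(t, 700.0))
        for t, free in zip(theta, _FREE[family])
    )


def _to_working(family, params):
    return np.array(
        [p if free else math.log(p) for p, free in zip(params, _FREE[family])]
    )


def _starts(family, time, event):
    t_ev = time[event]
    total = float(time.sum())
    rate = max(event.sum() / total, 1e-8)
    mu = float(np.mean(np.log(t_ev)))
    sd = max(float(np.std(np.log(t_ev))), 0.1)
    med = float(np.median(t_ev))
    base = {
        "exponential": [(rate,)],
        "weibull": [(1.0, 1.0 / rate), (1.5, med / math.log(2) ** (1 / 1.5))],
        "gompertz": [(1e-3, rate), (-1e-3, rate), (0.05, rate / 2)],
        "loglogistic": [(1.0, med), (2.0, med)],
        "lognormal": [(mu, sd), (mu, 1.0)],
        "gengamma": [(mu, sd, 0.3), (mu, sd, -0.3), (mu, sd, 1.0)],
    }[family]
    return base


def _hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_parametric(time, event, family: str) -> FittedModel:
    """Fit one parametric family to right-censored data by ML.

    ``time`` (months, > 0) and ``event`` (1 = event, 0 = censored) are
    array-likes of equal length. The log-likelihood is the standard
    right-censoring form: events contribute log f(t), censored records
    log S(t). Standard errors come from the inverse observed information
    (numerical Hessian at the optimum, natural parameter scale).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.size == 0 or time.shape != event.shape:
        raise ValueError("time and event must be non-empty and aligned")
    if np.any(time <= 0):
        raise ValueError("times must be strictly positive")
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    if event.sum() == 0:
        raise FitError("no events observed; parametric fit is unidentified")

    def nll_working(theta):
        try:
            dist = ParametricSurvival(family, _to_natural(family, theta))
        except (ValueError, OverflowError):
            return np.inf
        return _neg_loglik(dist, time, event)

    best = None
    for start in _starts(family, time, event):
        x0 = _to_working(family, start)
        for method in ("Nelder-Mead", "L-BFGS-B"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    nll_working, x0, method=method,
                    options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-10}
                    if method == "Nelder-Mead" else {"maxiter": 500},
                )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
                best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"{family}: optimiser failed to converge from all starts")

    params = _to_natural(family, best.x)
    dist = ParametricSurvival(family, params)
    loglik = -float(best.fun)
    k = len(params)
    n = int(time.size)

    def nll_natural(p):
        try:
            return _neg_loglik(ParametricSurvival(family, tuple(p)), time, event)
        except ValueError:
            return np.inf

    se = tuple(float("nan") for _ in params)
    try:
        H = _hessian(nll_natural, np.asarray(params))
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se = tuple(float(s) for s in np.sqrt(d))
    except np.linalg.LinAlgError:
        pass

    return FittedModel(
        dist=ParametricSurvival(family, params, param_se=se),
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n=n,
        n_events=int(event.sum()),
    )


def fit_all_families(time, event, families=FAMILIES) -> list[FittedModel]:
    """Fit every requested family; families that fail to converge are skipped."""
    out = []
    for fam in families:
        try:
            out.append(fit_parametric(time, event, fam))
        except FitError:
            warnings.warn(f"{fam}: fit failed, excluded from selection")
    if not out:
        raise FitError("every candidate family failed to fit")
    return out


@dataclass(frozen=True)
class SelectionReport:
    best_aic: str
    best_bic: str
    agreement: bool
    table: tuple  # (family, loglik, aic, bic) rows sorted by AIC


def select_best(models: list[FittedModel]) -> SelectionReport:
    """Pick the family minimising AIC; BIC breaks AIC ties.

    The BIC winner is reported separately and ``agreement`` flags whether the
    two criteria choose the same family.
    """
    if len(models) < 2:
        raise ValueError("model selection needs at least two candidate fits")
    by_aic = sorted(models, key=lambda m: (m.aic, m.bic))
    by_bic = sorted(models, key=lambda m: (m.bic, m.aic))
    return SelectionReport(
        best_aic=by_aic[0].family,
        best_bic=by_bic[0].family,
        agreement=by_aic[0].family == by_bic[0].family,
        table=tuple((m.family, m.loglik, m.aic, m.bic) for m in by_aic),
    )


# ---------------------------------------------------------------------------
# Discounted person-time
# ---------------------------------------------------------------------------


def discounted_state_time(
    curve, horizon_years: float, rate_per_year: float, cycle_years: float
) -> float:
    """Discounted person-years under a survival curve over a finite horizon.

    Approximates the integral of S(t) (1+r)^(-t) dt over [0, horizon] by the
    trapezoid rule on the cycle grid. ``curve`` is any callable of time in
    months; the continuous discount factor is equivalent to a
    half-cycle-corrected discrete sum.
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    if rate_per_year < 0:
        raise ValueError("discount rate must be non-negative")
    n_cycles = int(round(horizon_years / cycle_years))
    t_years = np.linspace(0.0, n_cycles * cycle_years, n_cycles + 1)
    s = np.asarray(curve(t_years * 12.0), dtype=float)
    w = (1.0 + rate_per_year) ** (-t_years)
    return float(np.trapezoid(s * w, t_years))
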