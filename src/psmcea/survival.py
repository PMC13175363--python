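"""Parametric survival distributions, censored maximum likelihood, and
information-criterion model selection.

Five families are supported — exponential, Weibull, Gompertz, log-logistic
and lognormal — the candidate set conventionally screened when
extrapolating trial Kaplan–Meier curves for economic models.  Fitting
maximises the right-censored log-likelihood

    l(theta) = sum_{event} log f(t_i; theta) + sum_{censored} log S(t_i; theta)

with a small set of deterministic multi-starts from moment-style initial
values, optimised on a log scale for positivity-constrained parameters.
Model choice is by lowest AIC, ties broken by BIC then parsimony.  BIC uses
n = number of subjects (not events).

Parameterisations (time axis: months):

==============  ==========================  ==========================
family          params                      S(t)
==============  ==========================  ==========================
exponential     (rate,)                     exp(-rate*t)
weibull         (shape, scale)              exp(-(t/scale)**shape)
gompertz        (shape, rate)               exp(-(rate/shape)*(exp(shape*t)-1))
loglogistic     (shape, scale)              1 / (1 + (t/scale)**shape)
lognormal       (meanlog, sdlog)            1 - Phi((ln t - meanlog)/sdlog)
==============  ==========================  ==========================

The Gompertz shape may be negative (survival plateau at exp(rate/shape));
its shape->0 limit is the exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "FAMILIES",
    "IPDRecord",
    "SurvivalDistribution",
    "FittedModel",
    "SelectionResult",
    "ParameterDomainError",
    "FitConvergenceError",
    "survival_probability",
    "survival_function",
    "fit_parametric",
    "fit_all_families",
    "select_best",
    "median_survival",
    "read_ipd_csv",
    "write_ipd_csv",
    "fit_report",
]

FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
}

_TINY_TIME = 1e-10  # guard for log(t) at t == 0 in event likelihoods


class ParameterDomainError(ValueError):
    """Parameter vector outside the family's domain."""


class FitConvergenceError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class IPDRecord:
    """One (possibly right-censored) time-to-event observation in months."""

    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class SurvivalDistribution:
    """A parametric family plus its parameter vector (time in months)."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterDomainError(f"unknown family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if len(p) != _N_PARAMS[self.family]:
            raise ParameterDomainError(
                f"{self.family} takes {_N_PARAMS[self.family]} params, got {len(p)}"
            )
        _validate_params(self.family, p)

    def survival(self, t) -> np.ndarray | float:
        return survival_function(self, t)

    def median(self) -> float:
        return median_survival(self)


def _validate_params(family: str, p: tuple[float, ...]) -> None:
    if any(not math.isfinite(v) for v in p):
        raise ParameterDomainError(f"{family} params must be finite, got {p}")
    if family == "exponential" and p[0] <= 0:
        raise ParameterDomainError("exponential rate must be > 0")
    if family == "weibull" and (p[0] <= 0 or p[1] <= 0):
        raise ParameterDomainError("weibull shape and scale must be > 0")
    if family == "gompertz" and p[1] <= 0:
        raise ParameterDomainError("gompertz rate must be > 0")
    if family == "loglogistic" and (p[0] <= 0 or p[1] <= 0):
        raise ParameterDomainError("loglogistic shape and scale must be > 0")
    if family == "lognormal" and p[1] <= 0:
        raise ParameterDomainError("lognormal sdlog must be > 0")


# ---------------------------------------------------------------------------
# survival / density closed forms
# ---------------------------------------------------------------------------

def _log_survival(family: str, p: Sequence[float], t: np.ndarray) -> np.ndarray:
    """log S(t) vectorized; t must be >= 0."""
    if family == "exponential":
        (lam,) = p
        return -lam * t
    if family == "weibull":
        k, lam = p
        return -np.power(t / lam, k)
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-9:
            # exponential limit with first-order correction in a
            return -b * t * (1.0 + 0.5 * a * t)
        with np.errstate(over="ignore"):  # overflow -> -inf logS, S = 0
            return -(b / a) * np.expm1(a * t)
    if family == "loglogistic":
        beta, alpha = p
        return -np.log1p(np.power(t / alpha, beta))
    if family == "lognormal":
        mu, sig = p
        out = np.zeros_like(t, dtype=float)
        pos = t > 0
        z = (np.log(t[pos]) - mu) / sig
        out[pos] = special.log_ndtr(-z)
        return out
    raise ParameterDomainError(f"unknown family {family!r}")


def _log_density(family: str, p: Sequence[float], t: np.ndarray) -> np.ndarray:
    """log f(t) vectorized; t clipped away from 0."""
    t = np.maximum(t, _TINY_TIME)
    if family == "exponential":
        (lam,) = p
        return math.log(lam) - lam * t
    if family == "weibull":
        k, lam = p
        u = t / lam
        return math.log(k / lam) + (k - 1.0) * np.log(u) - np.power(u, k)
    if family == "gompertz":
        a, b = p
        # hazard h(t) = b * exp(a t)
        return math.log(b) + a * t + _log_survival(family, p, t)
    if family == "loglogistic":
        beta, alpha = p
        lu = np.log(t / alpha)
        return (
            math.log(beta / alpha)
            + (beta - 1.0) * lu
            - 2.0 * np.logaddexp(0.0, beta * lu)
        )
    if family == "lognormal":
        mu, sig = p
        z = (np.log(t) - mu) / sig
        return -0.5 * z * z - 0.5 * math.log(2 * math.pi) - math.log(sig) - np.log(t)
    raise ParameterDomainError(f"unknown family {family!r}")


def survival_function(dist: SurvivalDistribution, t) -> np.ndarray | float:
    """S(t) for scalar or array t (months); S(0) = 1 in every family."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(_log_survival(dist.family, dist.params, np.atleast_1d(arr)))
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if arr.ndim == 0 else out


def survival_probability(dist: SurvivalDistribution, t: float) -> float:
    """Scalar S(t)."""
    return float(survival_function(dist, float(t)))


def median_survival(dist: SurvivalDistribution) -> float:
    """Time t with S(t) = 0.5, in months.

    Closed forms exist for every family.  Returns NaN (an undefined-median
    signal, not an error) when the survival plateau sits above 0.5, which
    can happen for Gompertz with negative shape.
    """
    p = dist.params
    if dist.family == "exponential":
        return math.log(2.0) / p[0]
    if dist.family == "weibull":
        k, lam = p
        return lam * math.log(2.0) ** (1.0 / k)
    if dist.family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return math.log(2.0) / b
        arg = 1.0 + a * math.log(2.0) / b
        if arg <= 0:  # S(inf) = exp(b/a) > 0.5: median undefined
            return math.nan
        return math.log(arg) / a
    if dist.family == "loglogistic":
        return p[1]
    if dist.family == "lognormal":
        return math.exp(p[0])
    raise ParameterDomainError(f"unknown family {dist.family!r}")


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedModel:
    """A fitted parametric model with its information criteria.

    ``bic`` uses n = number of subjects contributing to the likelihood
    (events and censored records alike), not the event count.
    """

    distribution: SurvivalDistribution
    loglik: float
    n_subjects: int
    n_params: int
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "aic", 2.0 * self.n_params - 2.0 * self.loglik)
        object.__setattr__(
            self, "bic", self.n_params * math.log(self.n_subjects) - 2.0 * self.loglik
        )


@dataclass(frozen=True)
class SelectionResult:
    """Best model by (AIC, BIC, parsimony) with the full ranking."""

    best: FittedModel
    ranking: tuple[FittedModel, ...]


def _ipd_arrays(data: Iterable[IPDRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(data)
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=int)
    return t, e


def _neg_loglik(family: str, p: Sequence[float], t_ev, t_ce) -> float:
    try:
        _validate_params(family, tuple(p))
    except ParameterDomainError:
        return np.inf
    ll = 0.0
    if t_ev.size:
        ll += float(np.sum(_log_density(family, p, t_ev)))
    if t_ce.size:
        ll += float(np.sum(_log_survival(family, p, t_ce)))
    return -ll if math.isfinite(ll) else np.inf


# transform between optimizer scale (unconstrained) and natural parameters
def _to_natural(family: str, theta: np.ndarray) -> tuple[float, ...]:
    if family == "gompertz":
        return (float(theta[0]), float(math.exp(theta[1])))
    if family == "lognormal":
        return (float(theta[0]), float(math.exp(theta[1])))
    return tuple(float(math.exp(v)) for v in theta)


def _to_theta(family: str, p: Sequence[float]) -> np.ndarray:
    if family in ("gompertz", "lognormal"):
        return np.array([p[0], math.log(p[1])])
    return np.log(np.asarray(p, dtype=float))


def _starts(family: str, t: np.ndarray, e: np.ndarray) -> list[tuple[float, ...]]:
    """Deterministic moment-style multi-starts (natural scale)."""
    te = t[e == 1]
    tpos = np.maximum(te, _TINY_TIME)
    mean_t = float(np.mean(np.maximum(t, _TINY_TIME)))
    med_t = float(np.median(tpos))
    rate0 = float(e.sum()) / float(np.sum(np.maximum(t, _TINY_TIME)))
    if family == "exponential":
        return [(rate0,)]
    if family == "weibull":
        return [(1.0, mean_t), (0.8, mean_t), (1.5, mean_t)]
    if family == "gompertz":
        return [(1e-4, rate0), (0.05, rate0), (-0.05, rate0)]
    if family == "loglogistic":
        return [(1.2, med_t), (0.8, med_t), (2.0, med_t)]
    if family == "lognormal":
        mu0 = float(np.mean(np.log(tpos)))
        sig0 = float(np.std(np.log(tpos), ddof=1)) if tpos.size > 1 else 1.0
        sig0 = max(sig0, 1e-3)
        return [(mu0, sig0), (mu0, 2.0 * sig0), (mu0, 0.5 * sig0)]
    raise ParameterDomainError(f"unknown family {family!r}")


def fit_parametric(data: Iterable[IPDRecord], family: str) -> FittedModel:
    """Maximum-likelihood fit of one family to right-censored data.

    Requires at least two observed events.  The exponential rate has a
    closed-form MLE; the other families are optimised by L-BFGS-B on the
    log-parameter scale from three deterministic starts.
    """
    if family not in FAMILIES:
        raise ParameterDomainError(f"unknown family {family!r}")
    t, e = _ipd_arrays(data)
    if t.size == 0:
        raise ValueError("empty dataset")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if int(e.sum()) < 2:
        raise ValueError("need at least 2 observed events to fit")

    t_ev, t_ce = t[e == 1], t[e == 0]
    n = int(t.size)

    if family == "exponential":
        lam = float(e.sum()) / float(np.sum(np.maximum(t, _TINY_TIME)))
        dist = SurvivalDistribution("exponential", (lam,))
        ll = -_neg_loglik("exponential", dist.params, t_ev, t_ce)
        return FittedModel(dist, ll, n, 1)

    diagnostics = []
    best = None
    for start in _starts(family, t, e):
        theta0 = _to_theta(family, start)
        res = optimize.minimize(
            lambda th: _neg_loglik(family, _to_natural(family, th), t_ev, t_ce),
            theta0,
            method="L-BFGS-B",
        )
        diagnostics.append((start, res.success, float(res.fun), res.message))
        if res.success and math.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitConvergenceError(
            f"{family} fit failed to converge from all starts", diagnostics
        )
    params = _to_natural(family, best.x)
    dist = SurvivalDistribution(family, params)
    return FittedModel(dist, -float(best.fun), n, _N_PARAMS[family])


def fit_all_families(
    data: Iterable[IPDRecord], families: Sequence[str] = FAMILIES
) -> list[FittedModel]:
    """Fit every requested family; raises only if all of them fail."""
    data = list(data)
    out, errors = [], []
    for fam in families:
        try:
            out.append(fit_parametric(data, fam))
        except FitConvergenceError as exc:  # keep going; sweep-level concern
            errors.append((fam, exc))
    if not out:
        raise FitConvergenceError(f"every family failed: {errors}")
    return out


def select_best(models: Sequence[FittedModel]) -> SelectionResult:
    """Lowest AIC wins; ties broken by lowest BIC, then fewest parameters."""
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    ranking = tuple(sorted(models, key=lambda m: (m.aic, m.bic, m.n_params)))
    return SelectionResult(best=ranking[0], ranking=ranking)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ipd_csv(path: str | Path) -> list[IPDRecord]:
    """Read `time_months,event` CSV (header required)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_months", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"IPD CSV missing columns: {sorted(missing)}")
    return [
        IPDRecord(float(r.time_months), int(r.event)) for r in df.itertuples()
    ]


def write_ipd_csv(data: Iterable[IPDRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_months": [r.time for r in data], "event": [r.event for r in data]}
    )
    df.to_csv(path, index=False, float_format="%.17g")  # exact round trip


def fit_report(selection: SelectionResult) -> dict:
    """JSON-serialisable fit/selection report."""
    def one(m: FittedModel) -> dict:
        return {
            "family": m.distribution.family,
            "params": list(m.distribution.params),
            "loglik": m.loglik,
            "n_subjects": m.n_subjects,
            "n_params": m.n_params,
            "aic": m.aic,
            "bic": m.bic,
        }

    return {"best": one(selection.best), "ranking": [one(m) for m in selection.ranking]}
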