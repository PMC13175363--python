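"""Synthetic trial-data generator.

Emulates the statistical structure of a 2:1 randomized oncology trial
(230 vs 116 subjects) whose progression-free and overall survival follow
the packaged lognormal curves, so the full pipeline — digitization,
pseudo-IPD reconstruction, parametric refitting, model selection, and the
economic model itself — can be exercised end to end without any external
data.

Per-subject event times are coupled: the recorded PFS time is the minimum
of an independent progression draw and the subject's death time, so PFS
never exceeds OS at the individual level (independent marginal curves
would allow it).  Censoring combines uniform accrual with an
administrative data cutoff, plus optional exponential dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .km import DigitizedCurve, km_estimator
from .survival import IPDRecord, SurvivalDistribution

__all__ = ["TrialSimSpec", "simulate_trial", "make_digitized_curve"]

# Default generating curves: the packaged case study's lognormal fits
# (months).  Listed here so the generator is usable stand-alone.
_DEFAULT_CURVES = {
    "dual": {
        "pfs": SurvivalDistribution("lognormal", (2.11975, 0.96625)),
        "os": SurvivalDistribution("lognormal", (3.08907, 1.09587)),
    },
    "sorafenib": {
        "pfs": SurvivalDistribution("lognormal", (1.573341, 0.703413)),
        "os": SurvivalDistribution("lognormal", (2.61494, 1.09869)),
    },
}


@dataclass(frozen=True)
class TrialSimSpec:
    """Trial-generator settings (times in months)."""

    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {"dual": 230, "sorafenib": 116}
    )
    curves: dict[str, dict[str, SurvivalDistribution]] = field(
        default_factory=lambda: {a: dict(c) for a, c in _DEFAULT_CURVES.items()}
    )
    accrual_months: float = 12.0
    cutoff_months: float = 36.0
    dropout_rate_per_month: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_arm.values()):
            raise ValueError("arm sizes must be > 0")
        if self.dropout_rate_per_month < 0:
            raise ValueError("dropout rate must be >= 0")


def _draw_times(dist: SurvivalDistribution, n: int, rng: np.random.Generator):
    """Inverse-CDF sampling via the closed forms (lognormal drawn directly)."""
    if dist.family == "lognormal":
        mu, sig = dist.params
        return np.exp(rng.normal(mu, sig, size=n))
    u = rng.uniform(size=n)  # u = S(t): invert each family's survival
    if dist.family == "exponential":
        return -np.log(u) / dist.params[0]
    if dist.family == "weibull":
        k, lam = dist.params
        return lam * (-np.log(u)) ** (1.0 / k)
    if dist.family == "loglogistic":
        beta, alpha = dist.params
        return alpha * ((1.0 - u) / u) ** (1.0 / beta)
    if dist.family == "gompertz":
        a, b = dist.params
        arg = 1.0 - (a / b) * np.log(u)
        with np.errstate(invalid="ignore"):
            t = np.log(arg) / a
        t[~np.isfinite(t)] = np.inf  # plateau mass never fails (a < 0)
        return t
    raise ValueError(f"unknown family {dist.family!r}")


def simulate_trial(spec: TrialSimSpec) -> dict[str, dict[str, list[IPDRecord]]]:
    """Per-arm, per-endpoint IPD records; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict[str, list[IPDRecord]]] = {}
    for arm in sorted(spec.n_per_arm):
        n = spec.n_per_arm[arm]
        os_t = _draw_times(spec.curves[arm]["os"], n, rng)
        prog_t = _draw_times(spec.curves[arm]["pfs"], n, rng)
        pfs_t = np.minimum(prog_t, os_t)

        entry = rng.uniform(0.0, spec.accrual_months, size=n)
        admin = (
            spec.cutoff_months - entry
            if np.isfinite(spec.cutoff_months)
            else np.full(n, np.inf)
        )
        if spec.dropout_rate_per_month > 0:
            dropout = rng.exponential(1.0 / spec.dropout_rate_per_month, size=n)
        else:
            dropout = np.full(n, np.inf)
        cens = np.minimum(admin, dropout)

        out[arm] = {}
        for endpoint, times in (("pfs", pfs_t), ("os", os_t)):
            obs = np.minimum(times, cens)
            event = (times <= cens).astype(int)
            out[arm][endpoint] = [
                IPDRecord(float(t), int(e)) for t, e in zip(obs, event)
            ]
    return out


def make_digitized_curve(
    data: list[IPDRecord],
    n_points: int = 60,
    jitter: float = 0.005,
    rng: np.random.Generator | None = None,
) -> DigitizedCurve:
    """Sample the KM curve at ``n_points`` step times, with optional uniform
    jitter in S emulating plot-reading error.  A digitizer never reads an
    increasing survival curve, so jittered values are re-monotonized."""
    km = km_estimator(data)
    t, s = km.times, km.survival
    if len(t) - 1 > n_points:
        # keep t=0 and an even subset of the remaining step times
        idx = np.unique(
            np.round(np.linspace(1, len(t) - 1, n_points)).astype(int)
        )
        t = np.concatenate([[0.0], t[idx]])
        s = np.concatenate([[1.0], s[idx]])
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        s = s + rng.uniform(-jitter, jitter, size=s.shape)
        s[0] = 1.0
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    return DigitizedCurve(
        points=tuple(zip(t, s)), n_initial=len(data)
    )
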