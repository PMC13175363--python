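"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the comparison at each parameter's range limits
and ranks parameters by the spread in the ICER.  Probabilistic analysis
draws every parameter jointly — Gamma for costs, Beta for utilities and
adverse-event incidences, Normal for weight, a rescaled Beta for the
discount rate — with distributions moment-matched so the mean equals the
baseline and the SD is (max - min)/(2*1.96), i.e. the published range is
read as an approximate 95% interval.  Parameters are shared across arms
within a draw (common random numbers).

Cost-effectiveness acceptability curves use incremental net monetary
benefit, NMB(lambda) = lambda * dQALY - dCost, with exact ties split
evenly between the strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import UtilityInputs
from .model import CaseStudy, run_base_case

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PsaResult",
    "CeacCurve",
    "CrossoverResult",
    "InvariantViolation",
    "apply_params",
    "owsa",
    "sample_params",
    "run_psa",
    "ceac",
    "crossover_wtp",
    "plot_tornado",
    "plot_ce_plane",
    "plot_ceac",
]

log = logging.getLogger(__name__)

_DISTRIBUTIONS = ("gamma", "beta", "normal", "scaled_beta")


class InvariantViolation(ValueError):
    """A sampled/varied parameter set breaks a model invariant."""


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: range, distribution family and the slot it
    fills in the case study (``target`` path, e.g. ``price.finotonlimab``,
    ``utility.pd``, ``ae_incidence.dual.hypertension``)."""

    name: str
    target: str
    baseline: float
    low: float
    high: float
    distribution: str
    support: tuple[float, float] | None = None  # scaled_beta only

    def __post_init__(self):
        if not self.low <= self.baseline <= self.high:
            raise ValueError(
                f"{self.name}: need low <= baseline <= high, "
                f"got ({self.low}, {self.baseline}, {self.high})"
            )
        if self.distribution not in _DISTRIBUTIONS:
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "scaled_beta" and self.support is None:
            raise ValueError(f"{self.name}: scaled_beta requires a support interval")

    @property
    def sd(self) -> float:
        # published range read as an approximate 95% interval
        return (self.high - self.low) / (2.0 * 1.96)


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class CeacCurve:
    """Probability each strategy is cost-effective over a WTP grid."""

    wtp: np.ndarray
    p_reference: np.ndarray
    p_comparator: np.ndarray


@dataclass(frozen=True)
class CrossoverResult:
    wtp: float
    within_grid: bool


@dataclass(frozen=True)
class PsaResult:
    """Draw table (one row per Monte Carlo iteration) plus bookkeeping."""

    draws: pd.DataFrame
    seed: int
    n_resampled: int
    reference_arm: str
    comparator_arm: str


# ---------------------------------------------------------------------------
# applying parameter values to a case study
# ---------------------------------------------------------------------------

def apply_params(
    case: CaseStudy, values: dict[str, float], clamp_utilities: bool = False
) -> CaseStudy:
    """Return a copy of the case with named parameters replaced.

    With ``clamp_utilities`` the u_pd <= u_pfs ordering is restored by
    clamping (used in one-way analysis at range edges); otherwise a
    violating set raises :class:`InvariantViolation` (PSA resamples).
    """
    by_name = {p.name: p for p in case.params}
    unit_price = dict(case.econ.unit_price)
    ae_profile = {a: list(evs) for a, evs in case.econ.ae_profile.items()}
    econ_kw: dict = {}
    u_pfs, u_pd = case.utilities.u_pfs, case.utilities.u_pd
    spec = case.spec

    for name, value in values.items():
        target = by_name[name].target
        head, _, rest = target.partition(".")
        if head == "price":
            unit_price[rest] = value
        elif head == "cost":
            econ_kw[{"management": "management_cost_per_cycle",
                     "bsc": "bsc_cost_per_cycle",
                     "terminal": "terminal_cost"}[rest]] = value
        elif head == "ae_cost":
            for arm, evs in ae_profile.items():
                ae_profile[arm] = [
                    replace(ev, cost=value) if ev.name == rest else ev for ev in evs
                ]
        elif head == "ae_incidence":
            arm, _, ev_name = rest.partition(".")
            ae_profile[arm] = [
                replace(ev, incidence=value) if ev.name == ev_name else ev
                for ev in ae_profile[arm]
            ]
        elif head == "utility":
            if rest == "pfs":
                u_pfs = value
            else:
                u_pd = value
        elif head == "weight":
            econ_kw["weight_kg"] = value
        elif head == "discount_rate":
            spec = replace(spec, discount_rate_annual=value)
        else:
            raise ValueError(f"unknown parameter target {target!r}")

    if u_pd > u_pfs:
        if not clamp_utilities:
            raise InvariantViolation(f"u_pd={u_pd} > u_pfs={u_pfs}")
        log.warning("clamping u_pd %.4f to u_pfs %.4f at range edge", u_pd, u_pfs)
        u_pd = u_pfs

    econ = replace(
        case.econ,
        unit_price=unit_price,
        ae_profile={a: tuple(v) for a, v in ae_profile.items()},
        **econ_kw,
    )
    return case.evolve(
        econ=econ, utilities=UtilityInputs(u_pfs=u_pfs, u_pd=u_pd), spec=spec
    )


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------

def owsa(case: CaseStudy, params: list[ParamSpec] | None = None) -> list[TornadoEntry]:
    """Re-run the comparison at each parameter's low and high limit.

    Entries are sorted by descending ICER spread; exact ties keep the
    input (configuration) order.
    """
    params = list(params) if params is not None else list(case.params)
    entries = []
    for p in params:
        icers = {}
        for side, value in (("low", p.low), ("high", p.high)):
            varied = apply_params(case, {p.name: value}, clamp_utilities=True)
            icers[side] = run_base_case(varied).comparison.icer
        entries.append(TornadoEntry(p.name, icers["low"], icers["high"]))
    return sorted(entries, key=lambda e: -e.spread)


# ---------------------------------------------------------------------------
# probabilistic analysis
# ---------------------------------------------------------------------------

def _sampler(p: ParamSpec):
    """Build rng -> value for one parameter by moment matching."""
    m, sd = p.baseline, p.sd
    if sd == 0.0:
        return lambda rng: m
    if p.distribution == "gamma":
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return lambda rng: rng.gamma(shape, scale)
    if p.distribution == "normal":
        return lambda rng: rng.normal(m, sd)
    if p.distribution in ("beta", "scaled_beta"):
        lo, hi = p.support if p.distribution == "scaled_beta" else (0.0, 1.0)
        mm = (m - lo) / (hi - lo)
        ss = sd / (hi - lo)
        if ss * ss >= mm * (1.0 - mm):
            log.warning(
                "%s: beta moments infeasible (mean %.4f, sd %.4f); "
                "falling back to uniform(low, high)", p.name, mm, ss,
            )
            return lambda rng: rng.uniform(p.low, p.high)
        nu = mm * (1.0 - mm) / (ss * ss) - 1.0
        a, b = mm * nu, (1.0 - mm) * nu
        return lambda rng: lo + (hi - lo) * rng.beta(a, b)
    raise ValueError(f"unknown distribution {p.distribution!r}")


def sample_params(
    params: list[ParamSpec], rng: np.random.Generator
) -> dict[str, float]:
    """One joint draw of all parameters (independent across parameters)."""
    return {p.name: float(_sampler(p)(rng)) for p in params}


def run_psa(
    case: CaseStudy, n_iterations: int | None = None, seed: int = 0
) -> PsaResult:
    """Monte Carlo parameter uncertainty: n draws, both arms per draw.

    Draws violating model invariants (e.g. u_pd > u_pfs) are resampled and
    counted.  Identical seeds give bit-identical draw tables.
    """
    n = n_iterations if n_iterations is not None else case.psa.n_iterations
    rng = np.random.default_rng(seed)
    params = list(case.params)
    samplers = {p.name: _sampler(p) for p in params}
    ref, comp = case.reference_arm, case.comparator_arm

    rows = []
    n_resampled = 0
    for i in range(n):
        for _attempt in range(1000):
            values = {name: float(f(rng)) for name, f in samplers.items()}
            try:
                varied = apply_params(case, values, clamp_utilities=False)
                break
            except (InvariantViolation, ValueError):
                n_resampled += 1
        else:  # pragma: no cover - distributions make this unreachable
            raise RuntimeError("could not draw a valid parameter set")
        res = run_base_case(varied)
        row = {"draw": i, **values}
        for arm in (ref, comp):
            row[f"cost_{arm}"] = res.arm_results[arm].total_cost
            row[f"qaly_{arm}"] = res.arm_results[arm].total_qaly
        row["inc_cost"] = res.comparison.incremental_cost
        row["inc_qaly"] = res.comparison.incremental_qaly
        rows.append(row)
    if n_resampled:
        log.info("PSA resampled %d invalid draws", n_resampled)
    return PsaResult(
        draws=pd.DataFrame(rows),
        seed=seed,
        n_resampled=n_resampled,
        reference_arm=ref,
        comparator_arm=comp,
    )


def ceac(psa: PsaResult, wtp_grid: np.ndarray) -> CeacCurve:
    """Probability cost-effective vs WTP; ties in NMB split evenly."""
    wtp = np.asarray(wtp_grid, dtype=float)
    if psa.draws.empty:
        raise ValueError("no PSA draws")
    dq = psa.draws["inc_qaly"].to_numpy()
    dc = psa.draws["inc_cost"].to_numpy()
    nmb = wtp[:, None] * dq[None, :] - dc[None, :]
    p_ref = (np.mean(nmb > 0, axis=1) + 0.5 * np.mean(nmb == 0, axis=1))
    return CeacCurve(wtp=wtp, p_reference=p_ref, p_comparator=1.0 - p_ref)


def probability_cost_effective(psa: PsaResult, wtp: float) -> float:
    """CEAC evaluated at a single threshold."""
    return float(ceac(psa, np.array([wtp])).p_reference[0])


def crossover_wtp(curve: CeacCurve) -> CrossoverResult:
    """Smallest WTP where the reference strategy reaches probability 0.5,
    linearly interpolated; out-of-range flag with the boundary otherwise."""
    p = curve.p_reference
    idx = np.nonzero(p >= 0.5)[0]
    if idx.size == 0:
        return CrossoverResult(wtp=float(curve.wtp[-1]), within_grid=False)
    i = int(idx[0])
    if i == 0:
        return CrossoverResult(wtp=float(curve.wtp[0]), within_grid=False)
    w0, w1 = curve.wtp[i - 1], curve.wtp[i]
    p0, p1 = p[i - 1], p[i]
    frac = (0.5 - p0) / (p1 - p0) if p1 != p0 else 0.0
    return CrossoverResult(wtp=float(w0 + frac * (w1 - w0)), within_grid=True)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_tornado(entries: list[TornadoEntry], base_icer: float, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for y, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(y, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.name for e in entries], fontsize=8)
    ax.set_xlabel("ICER (CNY/QALY)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ce_plane(psa: PsaResult, wtp: float, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dq = psa.draws["inc_qaly"]
    dc = psa.draws["inc_cost"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=6, alpha=0.4)
    lim = max(abs(dq.min()), abs(dq.max())) * 1.1
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP {wtp:,.0f} CNY/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (CNY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, labels: tuple[str, str], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.p_reference, label=labels[0])
    ax.plot(curve.wtp, curve.p_comparator, label=labels[1])
    ax.set_xlabel("Willingness to pay (CNY/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
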