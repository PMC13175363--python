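"""Cost streams attached to the occupancy trace, and linear cost calibration.

Components (all CNY, discounted at the trace's cycle discount factors):

* drug acquisition — mg-exact pricing (no vial rounding), accrued over the
  progression-free share, either until progression or for a fixed number
  of treatment cycles;
* disease management (labs/imaging) — accrued over all alive states;
* best supportive care — accrued over the progressed (PD) share;
* subsequent-treatment residual — a flat per-cycle PD cost, normally set
  by calibration because published analyses rarely print the later-line
  drug mix behind their totals;
* terminal care — one-time at death, weighted by incident deaths;
* adverse-event management — one-time at model entry, undiscounted.

Calibration is two exact linear solves: the dual arm's total discounted
drug budget is back-solved from published price-sweep incremental costs
(incremental cost is linear in the retained price fraction with slope
minus the drug budget), converted into a fixed treatment duration; then
each arm's residual PD cost is solved so totals match the published base
case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .engine import ArmResult, ModelSpec, OccupancyTrace

__all__ = [
    "AdverseEvent",
    "DoseComponent",
    "DosingRule",
    "EconInputs",
    "CalibrationTargets",
    "CalibrationReport",
    "CalibrationError",
    "drug_cost_per_cycle",
    "ae_one_time_cost",
    "accumulate_costs",
    "calibrate_costs",
]

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Calibration produced a non-physical solution; carries the report."""

    def __init__(self, message: str, report: "CalibrationReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class AdverseEvent:
    """A Grade >=3 adverse event with one-time management cost."""

    name: str
    incidence: float  # fraction of patients
    cost: float       # CNY per event

    def __post_init__(self):
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"incidence must be in [0,1], got {self.incidence}")
        if self.cost < 0:
            raise ValueError("AE cost must be >= 0")


@dataclass(frozen=True)
class DoseComponent:
    drug: str
    mg_flat_per_cycle: float = 0.0
    mg_per_kg_per_cycle: float = 0.0


@dataclass(frozen=True)
class DosingRule:
    """Per-arm regimen; ``duration_cycles`` None means treat to progression,
    a float means a fixed (possibly fractional) number of on-treatment
    cycles — the latter is what cost calibration produces."""

    components: tuple[DoseComponent, ...]
    duration_cycles: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if self.duration_cycles is not None and self.duration_cycles < 0:
            raise ValueError("duration_cycles must be >= 0")


@dataclass(frozen=True)
class EconInputs:
    """Unit costs, weight and AE profiles (per arm), plus calibrated residuals."""

    unit_price: Mapping[str, float]              # CNY per mg
    management_cost_per_cycle: float
    bsc_cost_per_cycle: float
    terminal_cost: float
    weight_kg: float
    ae_profile: Mapping[str, tuple[AdverseEvent, ...]]   # arm -> events
    residual_pd_cost_per_cycle: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "unit_price", dict(self.unit_price))
        object.__setattr__(
            self, "ae_profile", {k: tuple(v) for k, v in self.ae_profile.items()}
        )
        object.__setattr__(
            self, "residual_pd_cost_per_cycle", dict(self.residual_pd_cost_per_cycle)
        )
        if any(v < 0 for v in self.unit_price.values()):
            raise ValueError("unit prices must be >= 0")
        for v in (self.management_cost_per_cycle, self.bsc_cost_per_cycle,
                  self.terminal_cost):
            if v < 0:
                raise ValueError("per-cycle/one-time costs must be >= 0")
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0")


def drug_cost_per_cycle(rule: DosingRule, inputs: EconInputs) -> float:
    """CNY per on-treatment cycle, mg-exact (no vial wastage)."""
    total = 0.0
    for comp in rule.components:
        mg = comp.mg_flat_per_cycle + comp.mg_per_kg_per_cycle * inputs.weight_kg
        total += mg * inputs.unit_price[comp.drug]
    return total


def ae_one_time_cost(inputs: EconInputs, arm: str) -> float:
    """Expected one-time adverse-event management cost for the arm."""
    return float(sum(ev.incidence * ev.cost for ev in inputs.ae_profile.get(arm, ())))


def _treatment_weights(n_cycles: int, duration_cycles: float | None) -> np.ndarray:
    """Fraction of each cycle spent on treatment under a fixed duration."""
    if duration_cycles is None:
        return np.ones(n_cycles)
    k = np.arange(n_cycles, dtype=float)  # cycle k covers (k, k+1] cycles
    return np.clip(duration_cycles - k, 0.0, 1.0)


def accumulate_costs(
    trace: OccupancyTrace,
    inputs: EconInputs,
    rule: DosingRule,
    spec: ModelSpec,
    arm: str,
) -> ArmResult:
    """Discounted cost components for one arm (QALY field left at 0)."""
    disc = trace.discount
    w_treat = _treatment_weights(trace.n_cycles, rule.duration_cycles)
    per_cycle_drug = drug_cost_per_cycle(rule, inputs)

    breakdown = {
        "drug": per_cycle_drug * float(np.sum(w_treat * trace.pfs_share * disc)),
        "management": inputs.management_cost_per_cycle
        * float(np.sum((trace.pfs_share + trace.pd_share) * disc)),
        "bsc": inputs.bsc_cost_per_cycle * float(np.sum(trace.pd_share * disc)),
        "subsequent": inputs.residual_pd_cost_per_cycle.get(arm, 0.0)
        * float(np.sum(trace.pd_share * disc)),
        "terminal": inputs.terminal_cost
        * float(np.sum(trace.incident_deaths * disc)),
        "ae": ae_one_time_cost(inputs, arm),
    }
    return ArmResult(
        total_cost=float(sum(breakdown.values())),
        total_qaly=0.0,
        cost_breakdown=breakdown,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTargets:
    """Published totals the calibrated model must reproduce."""

    total_cost: Mapping[str, float]                       # arm -> CNY
    incremental_cost_by_retained_fraction: Mapping[float, float]
    reference_arm: str = "dual"
    comparator_arm: str = "sorafenib"


@dataclass(frozen=True)
class CalibrationReport:
    drug_budget_estimates: dict[float, float]   # retained fraction -> C_drug
    drug_budget: float                          # pooled estimate (CNY)
    relative_spread: float                      # max pairwise disagreement
    duration_cycles: float                      # solved fixed duration, ref arm
    residual_pd_cost_per_cycle: dict[str, float]
    achieved_totals: dict[str, float]
    target_totals: dict[str, float]


def calibrate_costs(
    targets: CalibrationTargets,
    traces: Mapping[str, OccupancyTrace],
    inputs: EconInputs,
    rules: Mapping[str, DosingRule],
    spec: ModelSpec,
) -> tuple[EconInputs, dict[str, DosingRule], CalibrationReport]:
    """Exact linear calibration against published totals.

    Returns updated econ inputs (residual PD costs set), updated dosing
    rules (reference arm gets a fixed duration), and a report.  Raises
    :class:`CalibrationError` on negative durations or residuals.
    """
    ref = targets.reference_arm
    rows = dict(targets.incremental_cost_by_retained_fraction)
    ic_base = rows.pop(1.0)
    estimates = {
        f: (ic_base - ic) / (1.0 - f) for f, ic in rows.items() if f != 1.0
    }
    if not estimates:
        raise CalibrationError("need at least one non-unit retained fraction row")
    vals = np.array(list(estimates.values()))
    c_drug = float(vals.mean())
    spread = float((vals.max() - vals.min()) / c_drug) if c_drug else 0.0

    # duration such that the discounted on-treatment drug stream equals c_drug
    trace_ref = traces[ref]
    per_cycle = drug_cost_per_cycle(rules[ref], inputs)
    stream = per_cycle * trace_ref.pfs_share * trace_ref.discount
    cum = np.cumsum(stream)
    if c_drug < 0 or c_drug > cum[-1]:
        raise CalibrationError(
            f"drug budget {c_drug:.2f} outside attainable range [0, {cum[-1]:.2f}]"
        )
    m = int(np.searchsorted(cum, c_drug))
    prev = cum[m - 1] if m > 0 else 0.0
    duration = m + (c_drug - prev) / stream[m] if stream[m] > 0 else float(m)

    new_rules = dict(rules)
    new_rules[ref] = replace(rules[ref], duration_cycles=float(duration))

    # residual PD cost per arm: linear solve against target totals
    residuals: dict[str, float] = {}
    achieved: dict[str, float] = {}
    zeroed = replace(inputs, residual_pd_cost_per_cycle={})
    for arm, target in targets.total_cost.items():
        trace = traces[arm]
        base = accumulate_costs(trace, zeroed, new_rules[arm], spec, arm)
        pd_person_cycles = float(np.sum(trace.pd_share * trace.discount))
        if pd_person_cycles <= 0:
            raise CalibrationError(f"arm {arm!r} has no PD person-time to calibrate on")
        residuals[arm] = (target - base.total_cost) / pd_person_cycles
        achieved[arm] = base.total_cost + residuals[arm] * pd_person_cycles

    report = CalibrationReport(
        drug_budget_estimates=estimates,
        drug_budget=c_drug,
        relative_spread=spread,
        duration_cycles=float(duration),
        residual_pd_cost_per_cycle=dict(residuals),
        achieved_totals=achieved,
        target_totals=dict(targets.total_cost),
    )
    bad = {a: r for a, r in residuals.items() if r < 0}
    if bad:
        raise CalibrationError(f"negative residual PD costs: {bad}", report)
    log.info(
        "calibrated: drug budget %.2f CNY (spread %.4f%%), duration %.3f cycles",
        c_drug, 100 * spread, duration,
    )
    new_inputs = replace(inputs, residual_pd_cost_per_cycle=residuals)
    return new_inputs, new_rules, report
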