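"""Case-study container: everything needed to run both strategy arms.

A :class:`CaseStudy` bundles the model settings, survival curves, economic
inputs and sensitivity metadata for a two-strategy comparison.  The
packaged advanced-HCC study (finotonlimab + bevacizumab biosimilar versus
sorafenib) is loaded from the shipped YAML via :mod:`psmcea.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

from .costs import (
    CalibrationReport,
    CalibrationTargets,
    DosingRule,
    EconInputs,
    accumulate_costs,
    calibrate_costs,
)
from .engine import (
    ArmResult,
    Comparison,
    ModelSpec,
    OccupancyTrace,
    UtilityInputs,
    accumulate_qalys,
    compare,
    compute_occupancy,
)
from .survival import SurvivalDistribution

__all__ = ["PsaSettings", "ScenarioSettings", "CaseStudy", "BaseCaseResult",
           "run_arm", "run_base_case", "calibrate_case"]


@dataclass(frozen=True)
class PsaSettings:
    n_iterations: int = 1000
    wtp_grid_max: float = 1_500_000.0
    wtp_grid_step: float = 10_000.0


@dataclass(frozen=True)
class ScenarioSettings:
    horizons_years: tuple[float, ...] = (3, 4, 5, 6, 7, 8, 9, 10, 15)
    price_retained_fractions: tuple[float, ...] = (1.0, 0.7, 0.5, 0.3)
    families: tuple[str, ...] = (
        "exponential", "gompertz", "weibull", "loglogistic", "lognormal"
    )
    swept_drugs: tuple[str, ...] = ("finotonlimab", "bevacizumab")


@dataclass(frozen=True)
class CaseStudy:
    spec: ModelSpec
    utilities: UtilityInputs
    econ: EconInputs
    curves: Mapping[str, Mapping[str, SurvivalDistribution]]  # arm -> {pfs, os}
    rules: Mapping[str, DosingRule]
    reference_arm: str = "dual"
    comparator_arm: str = "sorafenib"
    params: tuple = ()  # sensitivity ParamSpec list (see psmcea.sensitivity)
    psa: PsaSettings = field(default_factory=PsaSettings)
    scenarios: ScenarioSettings = field(default_factory=ScenarioSettings)
    calibration_targets: CalibrationTargets | None = None

    def __post_init__(self):
        object.__setattr__(self, "curves", {a: dict(c) for a, c in self.curves.items()})
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "params", tuple(self.params))

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.curves.keys())

    def evolve(self, **changes: Any) -> "CaseStudy":
        return replace(self, **changes)


@dataclass(frozen=True)
class BaseCaseResult:
    arm_results: dict[str, ArmResult]
    comparison: Comparison


def run_arm(case: CaseStudy, arm: str, spec: ModelSpec | None = None) -> ArmResult:
    """Occupancy, discounted QALYs and discounted costs for one arm."""
    spec = spec or case.spec
    trace = compute_occupancy(case.curves[arm]["pfs"], case.curves[arm]["os"], spec)
    qaly = accumulate_qalys(trace, case.utilities, spec)
    cost_result = accumulate_costs(trace, case.econ, case.rules[arm], spec, arm)
    return replace(cost_result, total_qaly=qaly)


def run_base_case(case: CaseStudy, spec: ModelSpec | None = None) -> BaseCaseResult:
    """Both arms plus the incremental comparison (reference vs comparator)."""
    results = {arm: run_arm(case, arm, spec) for arm in case.arms}
    cmp_ = compare(results[case.reference_arm], results[case.comparator_arm])
    return BaseCaseResult(arm_results=results, comparison=cmp_)


def occupancy_traces(case: CaseStudy, spec: ModelSpec | None = None) -> dict[str, OccupancyTrace]:
    spec = spec or case.spec
    return {
        arm: compute_occupancy(c["pfs"], c["os"], spec)
        for arm, c in case.curves.items()
    }


def calibrate_case(case: CaseStudy) -> tuple["CaseStudy", CalibrationReport]:
    """Calibrate residual costs / treatment duration against the packaged
    published totals; returns the calibrated case and the report."""
    if case.calibration_targets is None:
        raise ValueError("case study carries no calibration targets")
    traces = occupancy_traces(case)
    econ, rules, report = calibrate_costs(
        case.calibration_targets, traces, case.econ, case.rules, case.spec
    )
    return case.evolve(econ=econ, rules=rules), report
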