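"""Scenario sweeps: time horizon, survival-distribution family, drug price.

Each sweep varies exactly one setting and re-runs the full comparison;
every non-swept input is left untouched.  The price sweep is parameterised
by the *retained* price fraction (a "30% price reduction" is retained
fraction 0.7), which keeps incremental cost exactly linear with slope
minus the discounted drug budget of the reference arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .engine import Comparison
from .model import CaseStudy, run_base_case
from .survival import (
    FitConvergenceError,
    IPDRecord,
    SurvivalDistribution,
    fit_parametric,
)

__all__ = ["ScenarioResult", "horizon_sweep", "distribution_sweep", "price_sweep",
           "sweep_table"]


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    total_cost: dict[str, float]
    total_qaly: dict[str, float]
    comparison: Comparison | None
    failed: bool = False
    failure_reason: str = ""


def _run(case: CaseStudy, label: str) -> ScenarioResult:
    res = run_base_case(case)
    return ScenarioResult(
        label=label,
        total_cost={a: r.total_cost for a, r in res.arm_results.items()},
        total_qaly={a: r.total_qaly for a, r in res.arm_results.items()},
        comparison=res.comparison,
    )


def horizon_sweep(
    case: CaseStudy, horizons_years: Sequence[float] | None = None
) -> list[ScenarioResult]:
    """One result per time horizon, everything else fixed."""
    horizons = horizons_years if horizons_years is not None else case.scenarios.horizons_years
    return [
        _run(case.evolve(spec=case.spec.with_horizon(h)), label=f"{h:g}y")
        for h in horizons
    ]


def price_sweep(
    case: CaseStudy,
    retained_fractions: Sequence[float] | None = None,
    drugs: Sequence[str] | None = None,
) -> list[ScenarioResult]:
    """Scale the reference arm's drug prices by each retained fraction."""
    fractions = (
        retained_fractions
        if retained_fractions is not None
        else case.scenarios.price_retained_fractions
    )
    drugs = tuple(drugs) if drugs is not None else case.scenarios.swept_drugs
    out = []
    for f in fractions:
        prices = dict(case.econ.unit_price)
        for d in drugs:
            prices[d] = case.econ.unit_price[d] * f
        varied = case.evolve(econ=replace(case.econ, unit_price=prices))
        out.append(_run(varied, label=f"retained={f:g}"))
    return out


def distribution_sweep(
    case: CaseStudy,
    families: Sequence[str] | None = None,
    ipd_by_curve: Mapping[str, Mapping[str, Iterable[IPDRecord]]] | None = None,
    params_by_family: Mapping[str, Mapping[str, Mapping[str, SurvivalDistribution]]] | None = None,
) -> list[ScenarioResult]:
    """Apply one parametric family to all four curves at a time.

    Curves come either from refitting supplied IPD (``ipd_by_curve``:
    arm -> endpoint -> records) or from externally supplied per-family
    parameters (``params_by_family``: family -> arm -> endpoint -> dist).
    A family whose fit fails is marked failed and the sweep continues.
    """
    families = tuple(families) if families is not None else case.scenarios.families
    if ipd_by_curve is None and params_by_family is None:
        raise ValueError("need IPD to refit or per-family parameters")
    out = []
    for fam in families:
        try:
            if params_by_family is not None:
                curves = params_by_family[fam]
            else:
                curves = {
                    arm: {
                        ep: fit_parametric(records, fam).distribution
                        for ep, records in endpoints.items()
                    }
                    for arm, endpoints in ipd_by_curve.items()
                }
            out.append(_run(case.evolve(curves=curves), label=fam))
        except (FitConvergenceError, KeyError, ValueError) as exc:
            out.append(
                ScenarioResult(
                    label=fam, total_cost={}, total_qaly={}, comparison=None,
                    failed=True, failure_reason=str(exc),
                )
            )
    return out


def sweep_table(results: Sequence[ScenarioResult], reference_arm: str,
                comparator_arm: str) -> pd.DataFrame:
    """Long-format table mirroring the published scenario layouts."""
    rows = []
    for r in results:
        if r.failed:
            rows.append({"scenario": r.label, "failed": True,
                         "failure_reason": r.failure_reason})
            continue
        rows.append({
            "scenario": r.label,
            "failed": False,
            f"cost_{reference_arm}": r.total_cost[reference_arm],
            f"cost_{comparator_arm}": r.total_cost[comparator_arm],
            f"qaly_{reference_arm}": r.total_qaly[reference_arm],
            f"qaly_{comparator_arm}": r.total_qaly[comparator_arm],
            "incremental_cost": r.comparison.incremental_cost,
            "incremental_qaly": r.comparison.incremental_qaly,
            "icer": r.comparison.icer,
        })
    return pd.DataFrame(rows)
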