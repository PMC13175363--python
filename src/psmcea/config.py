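"""Schema-validated case-study configuration (YAML or JSON).

The packaged ``hcc_finotonlimab.yaml`` holds the full advanced-HCC study:
lognormal survival parameters per arm/endpoint, unit costs and dosing,
utilities, the adverse-event profile, sensitivity ranges/distributions,
PSA and scenario settings, and the published totals used as calibration
targets.  Unknown keys are rejected; validation reports every violation,
not just the first.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import model as _model
from .costs import (
    AdverseEvent,
    CalibrationTargets,
    DoseComponent,
    DosingRule,
    EconInputs,
)
from .engine import ModelSpec, UtilityInputs
from .sensitivity import ParamSpec
from .survival import SurvivalDistribution

__all__ = [
    "CaseStudyConfig",
    "load_config",
    "load_case_study",
    "case_study_path",
    "config_hash",
]

_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CurveConfig(_Strict):
    family: Literal["exponential", "weibull", "gompertz", "loglogistic", "lognormal"]
    params: dict[str, float]

    @model_validator(mode="after")
    def _check_params(self):
        expected = set(_PARAM_NAMES[self.family])
        if set(self.params) != expected:
            raise ValueError(
                f"{self.family} curve needs params {sorted(expected)}, "
                f"got {sorted(self.params)}"
            )
        return self

    def to_distribution(self) -> SurvivalDistribution:
        order = _PARAM_NAMES[self.family]
        return SurvivalDistribution(self.family, tuple(self.params[k] for k in order))


class DoseComponentConfig(_Strict):
    drug: str
    mg_flat_per_cycle: float = 0.0
    mg_per_kg_per_cycle: float = 0.0


class DosingConfig(_Strict):
    components: list[DoseComponentConfig]
    duration: Literal["to_progression"] | float = "to_progression"


class ArmConfig(_Strict):
    label: str
    pfs: CurveConfig
    os: CurveConfig
    dosing: DosingConfig


class ModelConfig(_Strict):
    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    discount_rate_annual: float = Field(0.045, ge=0.0, le=1.0)
    half_cycle_correction: bool = True
    wtp_cny_per_qaly: float = 299_400.0


class UtilityConfig(_Strict):
    pfs: float = Field(ge=0.0, le=1.0)
    pd: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.pd > self.pfs:
            raise ValueError(
                f"utilities.pd ({self.pd}) must not exceed utilities.pfs ({self.pfs})"
            )
        return self


class CostConfig(_Strict):
    unit_price_cny_per_mg: dict[str, float]
    management_cny_per_cycle: float
    bsc_cny_per_cycle: float
    terminal_cny: float
    weight_kg: float


class AdverseEventConfig(_Strict):
    name: str
    incidence: float = Field(ge=0.0, le=1.0)
    cost_cny: float = Field(ge=0.0)


class SensitivityParamConfig(_Strict):
    name: str
    target: str
    baseline: float
    min: float
    max: float
    distribution: Literal["gamma", "beta", "normal", "scaled_beta"]
    support: tuple[float, float] | None = None

    @model_validator(mode="after")
    def _range(self):
        if not self.min <= self.baseline <= self.max:
            raise ValueError(
                f"parameter {self.name}: need min <= baseline <= max, "
                f"got ({self.min}, {self.baseline}, {self.max})"
            )
        return self


class PsaConfig(_Strict):
    n_iterations: int = Field(1000, gt=0)
    wtp_grid_max_cny: float = 1_500_000.0
    wtp_grid_step_cny: float = 10_000.0


class ScenarioConfig(_Strict):
    horizons_years: list[float] = [3, 4, 5, 6, 7, 8, 9, 10, 15]
    price_retained_fractions: list[float] = [1.0, 0.7, 0.5, 0.3]
    families: list[str] = [
        "exponential", "gompertz", "weibull", "loglogistic", "lognormal"
    ]
    swept_drugs: list[str] = ["finotonlimab", "bevacizumab"]


class CalibrationConfig(_Strict):
    total_cost_cny: dict[str, float]
    incremental_cost_cny_by_retained_fraction: dict[float, float]


class CaseStudyConfig(_Strict):
    """Top-level validated configuration."""

    name: str
    model: ModelConfig
    reference_arm: str
    comparator_arm: str
    arms: dict[str, ArmConfig]
    utilities: UtilityConfig
    costs: CostConfig
    adverse_events: dict[str, list[AdverseEventConfig]]
    sensitivity_params: list[SensitivityParamConfig]
    psa: PsaConfig = PsaConfig()
    scenarios: ScenarioConfig = ScenarioConfig()
    calibration_targets: CalibrationConfig | None = None

    @model_validator(mode="after")
    def _arms_consistent(self):
        for arm in (self.reference_arm, self.comparator_arm):
            if arm not in self.arms:
                raise ValueError(f"arm {arm!r} not defined under 'arms'")
        for arm in self.adverse_events:
            if arm not in self.arms:
                raise ValueError(f"adverse_events references unknown arm {arm!r}")
        return self

    def to_case_study(self) -> "_model.CaseStudy":
        spec = ModelSpec(
            cycle_length_days=self.model.cycle_length_days,
            horizon_years=self.model.horizon_years,
            discount_rate_annual=self.model.discount_rate_annual,
            half_cycle_correction=self.model.half_cycle_correction,
            wtp_threshold=self.model.wtp_cny_per_qaly,
        )
        econ = EconInputs(
            unit_price=self.costs.unit_price_cny_per_mg,
            management_cost_per_cycle=self.costs.management_cny_per_cycle,
            bsc_cost_per_cycle=self.costs.bsc_cny_per_cycle,
            terminal_cost=self.costs.terminal_cny,
            weight_kg=self.costs.weight_kg,
            ae_profile={
                arm: tuple(
                    AdverseEvent(ev.name, ev.incidence, ev.cost_cny) for ev in evs
                )
                for arm, evs in self.adverse_events.items()
            },
        )
        curves = {
            arm: {"pfs": a.pfs.to_distribution(), "os": a.os.to_distribution()}
            for arm, a in self.arms.items()
        }
        rules = {
            arm: DosingRule(
                components=tuple(
                    DoseComponent(c.drug, c.mg_flat_per_cycle, c.mg_per_kg_per_cycle)
                    for c in a.dosing.components
                ),
                duration_cycles=(
                    None if a.dosing.duration == "to_progression"
                    else float(a.dosing.duration)
                ),
            )
            for arm, a in self.arms.items()
        }
        params = tuple(
            ParamSpec(
                name=p.name, target=p.target, baseline=p.baseline,
                low=p.min, high=p.max, distribution=p.distribution,
                support=p.support,
            )
            for p in self.sensitivity_params
        )
        targets = None
        if self.calibration_targets is not None:
            targets = CalibrationTargets(
                total_cost=self.calibration_targets.total_cost_cny,
                incremental_cost_by_retained_fraction=(
                    self.calibration_targets.incremental_cost_cny_by_retained_fraction
                ),
                reference_arm=self.reference_arm,
                comparator_arm=self.comparator_arm,
            )
        return _model.CaseStudy(
            spec=spec,
            utilities=UtilityInputs(self.utilities.pfs, self.utilities.pd),
            econ=econ,
            curves=curves,
            rules=rules,
            reference_arm=self.reference_arm,
            comparator_arm=self.comparator_arm,
            params=params,
            psa=_model.PsaSettings(
                n_iterations=self.psa.n_iterations,
                wtp_grid_max=self.psa.wtp_grid_max_cny,
                wtp_grid_step=self.psa.wtp_grid_step_cny,
            ),
            scenarios=_model.ScenarioSettings(
                horizons_years=tuple(self.scenarios.horizons_years),
                price_retained_fractions=tuple(self.scenarios.price_retained_fractions),
                families=tuple(self.scenarios.families),
                swept_drugs=tuple(self.scenarios.swept_drugs),
            ),
            calibration_targets=targets,
        )


def load_config(path: str | Path) -> CaseStudyConfig:
    """Load and validate a YAML/JSON case-study configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    return CaseStudyConfig.model_validate(raw)


def case_study_path() -> Path:
    """Path of the packaged advanced-HCC case-study configuration."""
    return Path(resources.files("psmcea") / "data" / "hcc_finotonlimab.yaml")


def load_case_study() -> "_model.CaseStudy":
    """The packaged advanced-HCC case study as a runtime CaseStudy."""
    return load_config(case_study_path()).to_case_study()


def config_hash(cfg: CaseStudyConfig) -> str:
    """Stable SHA-256 over the canonical JSON dump."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
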