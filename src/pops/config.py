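"""Configuration schema and YAML loading.

A run configuration declares, in one YAML document, everything a PoPS
computation needs: the structural model and its typical parameter values
with units, the outer-loop uncertainty distributions, the between-subject
variability, the success criteria, the simulation plan (M, N, dose grid,
seed), and optionally a scenario grid and/or a PTA comparison.  The schema
is validated up front — unknown keys are rejected and criterion endpoints
are checked against the chosen model's output schema — so a run cannot fail
halfway through a long simulation on a typo.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import ConfigurationError
from .structural import get_model, known_models

__all__ = ["RunConfig", "load_config", "dump_config", "DistSpec"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DistSpec(_Strict):
    """Serialized uncertainty distribution: ``{family: ..., params: {...}}``."""

    family: str
    params: dict[str, Any]
    units: str = ""

    def to_dist(self):
        from .distributions import UncertaintyDist

        return UncertaintyDist(self.family, self.params, self.units)


class CorrelationCfg(_Strict):
    parameters: list[str]
    matrix: list[list[float]]


class ModelCfg(_Strict):
    kind: str
    params: dict[str, float]

    @field_validator("kind")
    @classmethod
    def _known(cls, v: str) -> str:
        try:
            get_model(v)
        except ConfigurationError:
            raise ValueError(f"unknown structural model {v!r}; known models: {list(known_models())}")
        return v


class BSVCfg(_Strict):
    cv: float | DistSpec
    scale: Literal["lognormal", "normal"] = "lognormal"

    @field_validator("cv")
    @classmethod
    def _nonneg(cls, v):
        if not isinstance(v, DistSpec) and v < 0:
            raise ValueError(f"cv must be >= 0, got {v}")
        return v


class ConditionCfg(_Strict):
    endpoint: str
    comparator: Literal[">", ">=", "<", "<="]
    threshold: float | DistSpec
    transform: str | None = None


class CriterionCfg(_Strict):
    label: str
    kind: Literal["benefit", "risk"]
    required_proportion: float | DistSpec
    conditions: list[ConditionCfg] = Field(min_length=1)
    proportion_inclusive: bool | None = None


class PlanCfg(_Strict):
    m: int = Field(500, ge=1)
    n: int = Field(1000, ge=1)
    doses: list[float] = Field(min_length=1)
    tau: float = Field(24.0, gt=0)
    route: Literal["oral", "iv_bolus"] = "oral"
    n_doses: int = Field(1, ge=1)
    seed: int = 0
    common_random_numbers: bool = True

    @field_validator("doses")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(f"doses must be strictly increasing, got {v}")
        return v


class ScenariosCfg(_Strict):
    # axis name -> level name -> {dotted config path: value}
    axes: dict[str, dict[str, dict[str, Any]]]


class PTAPopulationCfg(_Strict):
    """One arm of a PTA comparison: population PK + a MIC distribution."""

    cl_f: float = Field(gt=0)
    cv: float = Field(0.0, ge=0)
    dose: float = Field(gt=0)
    tau: float = Field(24.0, gt=0)
    mic: DistSpec | None = None  # lognormal on ln(MIC): params mu, sigma
    mic_table: dict[str, list[float]] | str | None = None  # inline table or CSV path

    @model_validator(mode="after")
    def _one_mic_source(self):
        if (self.mic is None) == (self.mic_table is None):
            raise ValueError("give exactly one of 'mic' or 'mic_table'")
        return self


class PTACfg(_Strict):
    n: int = Field(3000, ge=1)
    index: Literal["auc_mic", "cmax_mic", "t_above_mic"] = "auc_mic"
    target_quantile: float = Field(0.1, ge=0.0, le=1.0)
    round_mic_to_dilution: bool = False
    candidate: PTAPopulationCfg
    benchmark: PTAPopulationCfg
    seed: int = 0


class RunConfig(_Strict):
    """Top-level validated configuration (see module docstring)."""

    name: str = "unnamed"
    description: str = ""
    units: dict[str, str] = Field(default_factory=dict)
    model: ModelCfg | None = None
    uncertainty: dict[str, DistSpec] = Field(default_factory=dict)
    uncertainty_correlation: CorrelationCfg | None = None
    bsv: dict[str, BSVCfg] = Field(default_factory=dict)
    bsv_correlation: CorrelationCfg | None = None
    criteria: list[CriterionCfg] = Field(default_factory=list)
    plan: PlanCfg | None = None
    scenarios: ScenariosCfg | None = None
    pta: PTACfg | None = None

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.model is not None:
            schema = get_model(self.model.kind)
            for i, crit in enumerate(self.criteria):
                for j, cond in enumerate(crit.conditions):
                    if cond.endpoint not in schema.endpoint_names:
                        raise ValueError(
                            f"criteria[{i}].conditions[{j}].endpoint {cond.endpoint!r} is not "
                            f"produced by model {self.model.kind!r} "
                            f"(schema: {list(schema.endpoint_names)})"
                        )
            for name in list(self.uncertainty) + list(self.bsv):
                if name not in schema.param_names:
                    raise ValueError(
                        f"parameter {name!r} is not a parameter of model {self.model.kind!r} "
                        f"(parameters: {list(schema.param_names)})"
                    )
        if self.model is None and self.pta is None:
            raise ValueError("configuration needs a 'model' section or a 'pta' section")
        if self.model is not None and self.plan is None:
            raise ValueError("a 'model' section requires a 'plan' section")
        if self.model is not None and not self.criteria:
            raise ValueError("a 'model' section requires at least one criterion")
        labels = [c.label for c in self.criteria]
        if len(set(labels)) != len(labels):
            raise ValueError(f"criterion labels must be unique, got {labels}")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path} does not contain a mapping at top level")
    return validate_config(raw, source=str(path))


def validate_config(raw: Mapping[str, Any], source: str = "<dict>") -> RunConfig:
    try:
        return RunConfig.model_validate(dict(raw))
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigurationError(f"invalid configuration ({source}):\n  " + "\n  ".join(lines)) from exc


def dump_config(config: RunConfig) -> str:
    """Serialize a configuration back to YAML (round-trips through load)."""
    return yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=False)
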