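"""Run configuration: YAML files merging parameter overrides and scenario
settings onto the calibrated defaults.

Schema (all sections optional)::

    parameters:         # overrides keyed by ParameterSet field names
      Ca_ecs: 1300.0
    scenario:
      ca_mit: 0.25      # uM
      t_max: 1800.0     # s
      output_dt: 0.25   # s
      alpha_er: 1.0
      alpha_mit: 1.0
      alpha_pm: 1.0
    output_dir: results
    verbosity: 1

Unknown keys anywhere are rejected with a descriptive error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .params import ParameterSet, default_parameters

__all__ = ["Scenario", "RunConfig", "load_config", "save_config"]

_PARAM_FIELDS = {f.name for f in fields(ParameterSet)}


@dataclass(frozen=True)
class Scenario:
    ca_mit: float = 0.1         # uM, mitochondrial free calcium
    t_max: float = 1800.0       # s
    output_dt: float = 0.5      # s
    alpha_er: float = 1.0
    alpha_mit: float = 1.0
    alpha_pm: float = 1.0

    def __post_init__(self):
        if self.ca_mit <= 0 or self.t_max <= 0 or self.output_dt <= 0:
            raise ValueError("ca_mit, t_max and output_dt must be positive")


@dataclass(frozen=True)
class RunConfig:
    parameters: dict = field(default_factory=dict)   # overrides only
    scenario: Scenario = field(default_factory=Scenario)
    output_dir: str = "results"
    verbosity: int = 1

    def parameter_set(self) -> ParameterSet:
        """Defaults with overrides and the scenario applied (uncalibrated)."""
        p = default_parameters(**self.parameters)
        return p.replace(Ca_mit=self.scenario.ca_mit,
                         alpha_er=self.scenario.alpha_er,
                         alpha_mit=self.scenario.alpha_mit,
                         alpha_pm=self.scenario.alpha_pm)

    def overridden_keys(self) -> list:
        return sorted(self.parameters)

    def to_dict(self) -> dict:
        return {
            "parameters": dict(self.parameters),
            "scenario": dataclasses.asdict(self.scenario),
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }


def _check_keys(given: dict, allowed: set, where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}; "
            f"allowed: {', '.join(sorted(allowed))}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; ``None`` or an empty file yields pure defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ValueError(f"unparseable config {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    _check_keys(data, {"parameters", "scenario", "output_dir", "verbosity"},
                "config")
    overrides = data.get("parameters") or {}
    if not isinstance(overrides, dict):
        raise ValueError("'parameters' must be a mapping")
    _check_keys(overrides, _PARAM_FIELDS, "parameters")
    for k, v in overrides.items():
        if not isinstance(v, (int, float)):
            raise ValueError(f"parameter {k!r} must be numeric, got {v!r}")
    scen_raw = data.get("scenario") or {}
    _check_keys(scen_raw, {f.name for f in fields(Scenario)}, "scenario")
    scenario = Scenario(**{k: float(v) for k, v in scen_raw.items()})
    return RunConfig(parameters={k: float(v) for k, v in overrides.items()},
                     scenario=scenario,
                     output_dir=str(data.get("output_dir", "results")),
                     verbosity=int(data.get("verbosity", 1)))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
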