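"""Run configuration: YAML in, validated and fully resolved out.

Every defaulted field is echoed back in the resolved configuration that
each run writes next to its results, so no default is silent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .minicr import DEFAULT_RQ, minicr_model, validation_protocol
from .model import StimulusProtocol


class ConfigError(ValueError):
    pass


@dataclass
class ProtocolConfig:
    vco2: list[float] = field(default_factory=lambda: [0.3, 0.6, 0.9])
    rq: float = DEFAULT_RQ
    step_duration: float = 3000.0
    settle_window: float = 60.0

    def build(self) -> StimulusProtocol:
        levels = tuple((v / self.rq, v) for v in self.vco2)
        return StimulusProtocol(levels, self.step_duration, self.settle_window)


@dataclass
class ValidationProtocolConfig:
    vco2_start: float = 0.3
    vco2_stop: float = 1.0
    n_steps: int = 8
    rq: float = DEFAULT_RQ
    step_duration: float = 3000.0
    settle_window: float = 60.0

    def build(self) -> StimulusProtocol:
        return validation_protocol(
            self.vco2_start,
            self.vco2_stop,
            self.n_steps,
            self.rq,
            self.step_duration,
            self.settle_window,
        )


@dataclass
class CohortConfig:
    n_subjects: int = 20
    inter_subject_cv: float = 0.08
    measurement_cv: float = 0.05
    include_transients: bool = False
    truth_perturbation: dict[str, float] = field(default_factory=dict)  # name -> frac


@dataclass
class GridConfig:
    h: list[float] = field(default_factory=lambda: [-0.05, -0.025, 0.025, 0.05])


@dataclass
class OptimizerSettings:
    tol_fun: float = 1e-12
    tol_x: float = 1e-3
    max_fun_eval: int = 500
    max_restart: int = 10
    sigma0: float = 0.2
    max_iter: Optional[int] = None
    pop_size: Optional[int] = None


@dataclass
class RunConfig:
    model: str = "minicr"
    seed: int = 0
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    validation: ValidationProtocolConfig = field(default_factory=ValidationProtocolConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    epsilon: float = 1e-6
    bound_overrides: dict[str, list[float]] = field(default_factory=dict)

    def build_model(self):
        if self.model != "minicr":
            raise ConfigError(f"unknown model {self.model!r}")
        return minicr_model()

    def validate(self) -> None:
        model = self.build_model()
        known = set(model.registry.names)
        for name in self.bound_overrides:
            if name not in known:
                raise ConfigError(f"bound override for unknown parameter {name!r}")
        for name in self.cohort.truth_perturbation:
            if name not in known:
                raise ConfigError(f"truth perturbation for unknown parameter {name!r}")
        self.protocol.build()
        self.validation.build()

    # -- round-trip ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def sub(klass, key):
            return klass(**d[key]) if key in d else klass()

        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown configuration keys: {sorted(extra)}")
        cfg = cls(
            model=d.get("model", "minicr"),
            seed=int(d.get("seed", 0)),
            protocol=sub(ProtocolConfig, "protocol"),
            validation=sub(ValidationProtocolConfig, "validation"),
            cohort=sub(CohortConfig, "cohort"),
            grid=sub(GridConfig, "grid"),
            optimizer=sub(OptimizerSettings, "optimizer"),
            epsilon=float(d.get("epsilon", 1e-6)),
            bound_overrides=d.get("bound_overrides", {}),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError("configuration must be a mapping")
        return cls.from_dict(d)

    def write_resolved(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
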