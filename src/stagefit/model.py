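"""Simulator contract and core domain types.

A *model* in this framework is any object that exposes

* a :class:`ParameterRegistry` describing every parameter (nominal value,
  role, subsystem, mechanism tags, bound fractions, flags),
* a :class:`VariableSet` naming the observed steady-state outputs, and
* a ``steady_state(params, vo2, vco2)`` method returning one value per
  observed variable for a single stimulus level (oxygen uptake / carbon
  dioxide output pair, both in L/min).

Screening, selection, fitting and validation only ever talk to a model
through this surface, so the bundled demo model (:mod:`stagefit.minicr`)
and a full-scale physiological model are interchangeable.

Parameters are classified into exactly five roles:

``time_constant``
    governs transient speed only; never fitted against steady-state data.
``conversion``
    physical unit-conversion constants (never fitted).
``covariate``
    environment or subject characteristics taken directly from the
    experimental record (standardized, never optimized).
``initial_value``
    initial states of the transient integrator (never fitted).
``gain_threshold``
    gains and thresholds that modulate or saturate model mechanisms; the
    pool from which every fitted parameter is drawn.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace
from typing import Optional, Protocol, runtime_checkable

import numpy as np
import pandas as pd

ROLES = (
    "time_constant",
    "conversion",
    "covariate",
    "initial_value",
    "gain_threshold",
)


class SimulationError(RuntimeError):
    """Raised when a simulation cannot produce a finite steady state."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter.

    ``bounds`` are signed fractions of the nominal value, e.g. ``(-0.30,
    0.30)`` for the default +/-30% evaluation range.  ``excluded`` marks
    parameters that are clinically non-modifiable and must never enter any
    candidate set (the maximal-abdominal-pressure analogue).
    ``mechanisms`` is a possibly-empty tuple of ``(mechanism,
    regulatory_activity)`` tags used by the stimulus-related selection.
    """

    name: str
    nominal: float
    role: str
    subsystem: str
    units: str = ""
    mechanisms: tuple[tuple[str, str], ...] = ()
    bounds: tuple[float, float] = (-0.30, 0.30)
    fixed: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if not math.isfinite(self.nominal):
            raise ValueError(f"{self.name}: nominal must be finite")
        lo, up = self.bounds
        if not self.fixed and not lo < up:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")


class ParameterRegistry(Mapping[str, ParameterSpec]):
    """Ordered, name-keyed collection of :class:`ParameterSpec`.

    Iteration order is registration order; every ranking in the pipeline
    breaks ties by this order so results are deterministic.
    """

    def __init__(self, specs: Iterable[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate parameter {spec.name!r}")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [n for n, s in self._specs.items() if s.role == role]

    def candidates(self) -> list[str]:
        """Gain/threshold parameters eligible for fitting.

        Excluded and fixed parameters never appear in any candidate set.
        """
        return [
            n
            for n, s in self._specs.items()
            if s.role == "gain_threshold" and not s.excluded and not s.fixed
        ]

    def covariate_names(self) -> list[str]:
        return self.by_role("covariate")

    def subsystems(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self._specs.values():
            seen.setdefault(s.subsystem, None)
        return list(seen)

    def nominal_values(self) -> dict[str, float]:
        return {n: s.nominal for n, s in self._specs.items()}

    def with_updates(self, **changes: Mapping[str, object]) -> "ParameterRegistry":
        """Return a copy with per-parameter field overrides (name -> fields)."""
        specs = []
        for name, spec in self._specs.items():
            if name in changes:
                spec = replace(spec, **changes[name])  # type: ignore[arg-type]
            specs.append(spec)
        return ParameterRegistry(specs)

    # -- serialization --------------------------------------------------

    def to_json(self, path) -> None:
        payload = [
            {
                "name": s.name,
                "nominal": s.nominal,
                "role": s.role,
                "subsystem": s.subsystem,
                "units": s.units,
                "mechanisms": [list(m) for m in s.mechanisms],
                "bounds": list(s.bounds),
                "fixed": s.fixed,
                "excluded": s.excluded,
            }
            for s in self._specs.values()
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterRegistry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            ParameterSpec(
                name=d["name"],
                nominal=d["nominal"],
                role=d["role"],
                subsystem=d["subsystem"],
                units=d.get("units", ""),
                mechanisms=tuple(tuple(m) for m in d.get("mechanisms", [])),
                bounds=tuple(d.get("bounds", (-0.30, 0.30))),
                fixed=d.get("fixed", False),
                excluded=d.get("excluded", False),
            )
            for d in payload
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered exercise levels (VO2, VCO2 in L/min) and step timing.

    Levels are simulated as consecutive, equidistant, incremental steps of
    ``step_duration`` seconds; steady-state values are the signal average
    over the final ``settle_window`` seconds of each level.
    """

    levels: tuple[tuple[float, float], ...]
    step_duration: float = 3000.0
    settle_window: float = 60.0

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("protocol must have at least one level")
        vco2 = [lv[1] for lv in self.levels]
        if any(b <= a for a, b in zip(vco2, vco2[1:])):
            raise ValueError("levels must be strictly increasing in VCO2")
        if not self.step_duration >= self.settle_window > 0:
            raise ValueError("require step_duration >= settle_window > 0")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def vo2(self) -> tuple[float, ...]:
        return tuple(lv[0] for lv in self.levels)

    @property
    def vco2(self) -> tuple[float, ...]:
        return tuple(lv[1] for lv in self.levels)


@dataclass(frozen=True)
class VariableSet:
    """Ordered observed model outputs with units and owning subsystem."""

    names: tuple[str, ...]
    units: Mapping[str, str] = field(default_factory=dict)
    subsystems: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def subsystem_of(self, name: str) -> str:
        return self.subsystems.get(name, "")


@dataclass
class SteadyStateResponse:
    """Steady-state values, variables x levels, with provenance.

    ``values`` is a DataFrame indexed by variable name with 0-based level
    columns.  Reports use 1-based level numbering.
    """

    values: pd.DataFrame
    params: dict[str, float]
    protocol: StimulusProtocol

    def to_tidy(self) -> pd.DataFrame:
        """Long form with columns (level, variable, value); level is 1-based."""
        tidy = self.values.stack().rename("value").reset_index()
        tidy.columns = ["variable", "level", "value"]
        tidy["level"] = tidy["level"].astype(int) + 1
        return tidy[["level", "variable", "value"]]


@runtime_checkable
class Model(Protocol):
    """Contract every model definition must satisfy."""

    name: str
    registry: ParameterRegistry
    variables: VariableSet
    #: subsystem -> set of subsystems directly related to it (controller <->
    #: controlled system adjacency), used by the specific-selection rule.
    related_subsystems: Mapping[str, frozenset[str]]

    def steady_state(
        self, params: Mapping[str, float], vo2: float, vco2: float
    ) -> dict[str, float]: ...

    def time_constant(self, variable: str, params: Mapping[str, float]) -> float: ...

    def initial_state(
        self, params: Mapping[str, float], first_level: Mapping[str, float]
    ) -> dict[str, float]: ...


def complete_params(model: Model, params: Optional[Mapping[str, float]]) -> dict[str, float]:
    """Merge ``params`` over the registry nominals; reject unknown names."""
    full = model.registry.nominal_values()
    if params:
        unknown = set(params) - set(full)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        full.update(params)
    return full


def simulate_steady_state(
    model: Model,
    params: Optional[Mapping[str, float]] = None,
    protocol: Optional[StimulusProtocol] = None,
) -> SteadyStateResponse:
    """Steady-state response of ``model`` at every level of ``protocol``.

    For fixed-point models this is the exact per-level fixed point; the
    result is deterministic given ``(params, protocol)``.
    """
    if protocol is None:
        raise ValueError("protocol is required")
    full = complete_params(model, params)
    cols = {}
    for k, (vo2, vco2) in enumerate(protocol.levels):
        out = model.steady_state(full, vo2, vco2)
        for name, val in out.items():
            if not math.isfinite(val):
                raise SimulationError(
                    f"non-finite steady state for {name!r} at level {k + 1}"
                )
        cols[k] = [out[v] for v in model.variables.names]
    values = pd.DataFrame(cols, index=list(model.variables.names))
    return SteadyStateResponse(values=values, params=full, protocol=protocol)


def simulate_transient(
    model: Model,
    params: Optional[Mapping[str, float]] = None,
    protocol: Optional[StimulusProtocol] = None,
    sample_dt: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """First-order transient response across the protocol's steps.

    Each variable relaxes exponentially from its current value toward the
    steady state of the active level with the model-declared time constant.
    The update is the exact solution of ``dy/dt = (y_ss - y)/tau`` over one
    sample, so the integration cannot become unstable for any ``sample_dt``.

    Returns ``(times, frame)`` where ``frame`` is variables x samples.
    """
    if protocol is None:
        raise ValueError("protocol is required")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be positive")
    full = complete_params(model, params)
    ss = simulate_steady_state(model, full, protocol)
    names = list(model.variables.names)
    taus = np.array([model.time_constant(v, full) for v in names])
    if np.any(taus <= 0):
        raise SimulationError("time constants must be positive")

    first = dict(zip(names, ss.values[0].to_numpy()))
    y = np.array([model.initial_state(full, first)[v] for v in names], dtype=float)

    n_per = int(round(protocol.step_duration / sample_dt))
    total = n_per * protocol.n_levels + 1
    times = np.arange(total) * sample_dt
    out = np.empty((len(names), total))
    out[:, 0] = y
    decay = np.exp(-sample_dt / taus)
    i = 1
    for k in range(protocol.n_levels):
        target = ss.values[k].to_numpy()
        for _ in range(n_per):
            y = target + (y - target) * decay
            out[:, i] = y
            i += 1
    frame = pd.DataFrame(out, index=names, columns=times)
    return times, frame


def steady_state_from_transient(
    times: np.ndarray, frame: pd.DataFrame, protocol: StimulusProtocol
) -> pd.DataFrame:
    """Per-level steady-state values as the mean over each level's final
    ``settle_window`` seconds of a transient simulation."""
    cols = {}
    for k in range(protocol.n_levels):
        t_end = (k + 1) * protocol.step_duration
        mask = (times > t_end - protocol.settle_window) & (times <= t_end)
        cols[k] = frame.loc[:, mask].mean(axis=1)
    return pd.DataFrame(cols)
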