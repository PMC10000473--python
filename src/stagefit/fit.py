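"""Cost function, bounds, and the three sequential fitting stages.

The goodness-of-fit metric is a relative root-mean-square error over
stimulus levels, averaged over variables::

    CF = (1/I) sum_i sqrt( (1/K) sum_k ((y_exp_ik - y_sim_ik)/y_exp_ik)^2 )

It is dimensionless, zero exactly at a perfect match, and weights every
variable equally regardless of units.

Each selected parameter gets an evaluation range proportional to its
nominal value: +/-30% by default, overridable per parameter when
literature or mechanism constraints justify a different range.  CMA-ES
operates on coordinates scaled to [0, 1] over the bound range, with
initial step 0.2 in scaled units (equivalent to 0.2 (UB - LB)).

The three stages — base, specific, stimulus-related — run sequentially;
each stage optimizes only its own free parameters and freezes everything
fitted before it, so the cost is non-increasing across stage boundaries.
Restarts within a stage are chained: each restart resumes from the
incumbent best point with a geometrically shrunken initial step, making
the per-restart evaluation budget cumulative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cmaes import default_popsize, minimize_cmaes
from .cohort import SteadyStateDataset
from .model import Model, ParameterRegistry, SimulationError, StimulusProtocol, simulate_steady_state
from .select import SelectionPlan

STAGE_ORDER = ("base", "specific", "stimulus")
#: shrink factor for the initial step of successive chained restarts
RESTART_SIGMA_DECAY = 0.35


@dataclass(frozen=True)
class OptimizerConfig:
    """CMA-ES settings (one stage).

    ``max_iter`` and ``pop_size`` default to ``100 N^2`` and
    ``4 + floor(3 ln N)`` for N free parameters.  ``max_fun_eval`` is the
    per-restart function-evaluation budget.  ``sigma0`` is the initial
    coordinate-wise standard deviation in [0, 1]-scaled units, i.e. a
    fraction of each bound range.
    """

    seed: int
    tol_fun: float = 1e-12
    tol_x: float = 1e-3
    max_iter: Optional[int] = None
    max_fun_eval: int = 500
    max_restart: int = 10
    pop_size: Optional[int] = None
    sigma0: float = 0.2

    def __post_init__(self) -> None:
        if self.tol_fun <= 0 or self.tol_x <= 0 or self.sigma0 <= 0:
            raise ValueError("tolerances and sigma0 must be positive")
        if self.max_fun_eval <= 0 or self.max_restart < 0:
            raise ValueError("budgets must be positive")
        if self.pop_size is not None and self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")


@dataclass(frozen=True)
class Bound:
    """Evaluation range of one parameter.

    ``lower``/``upper`` are signed fractions of the nominal value;
    ``lo_abs``/``up_abs`` the resulting absolute bounds (ordered even for
    negative nominals).  ``source`` records which rule produced the range.
    """

    name: str
    nominal: float
    lower: float
    upper: float
    source: str = "default_pm30"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower fraction must be < upper")

    @property
    def lo_abs(self) -> float:
        a = self.nominal * (1 + self.lower)
        b = self.nominal * (1 + self.upper)
        return min(a, b)

    @property
    def up_abs(self) -> float:
        a = self.nominal * (1 + self.lower)
        b = self.nominal * (1 + self.upper)
        return max(a, b)


def build_bounds(
    params: list[str],
    registry: ParameterRegistry,
    overrides: Optional[Mapping[str, tuple[float, float]]] = None,
) -> dict[str, Bound]:
    """Default +/-30% ranges with per-parameter overrides.

    Overrides mirror literature-derived ranges (e.g. an elastance-like
    parameter allowed (-70%, +30%)); a registry spec whose own ``bounds``
    differ from the +/-30% default acts as a mechanism constraint.
    """
    overrides = overrides or {}
    out: dict[str, Bound] = {}
    for name in params:
        spec = registry[name]
        if name in overrides:
            lo, up = overrides[name]
            if not lo < up:
                raise ValueError(f"override for {name!r}: lower >= upper")
            out[name] = Bound(name, spec.nominal, lo, up, source="literature_override")
        elif spec.bounds != (-0.30, 0.30):
            lo, up = spec.bounds
            out[name] = Bound(name, spec.nominal, lo, up, source="mechanism_constraint")
        else:
            out[name] = Bound(name, spec.nominal, -0.30, 0.30)
        if abs(spec.nominal) == 0:
            raise ValueError(f"{name!r}: proportional bounds need a nonzero nominal")
    return out


def cost_function(y_exp: pd.DataFrame, y_sim: pd.DataFrame) -> float:
    """Relative-RMSE cost CF (see module docstring); 0 iff exact match."""
    y_sim = y_sim.reindex(index=y_exp.index)[y_exp.columns]
    e = y_exp.to_numpy(dtype=float)
    s = y_sim.to_numpy(dtype=float)
    if np.any(e == 0):
        bad = [
            (v, int(k) + 1)
            for vi, v in enumerate(y_exp.index)
            for ki, k in enumerate(y_exp.columns)
            if e[vi, ki] == 0
        ]
        raise ValueError(f"zero experimental value at (variable, level): {bad}")
    rel = (e - s) / e
    return float(np.mean(np.sqrt(np.mean(rel**2, axis=1))))


@dataclass
class FitResult:
    """Outcome of one fitting stage."""

    stage: str
    fitted: dict[str, float]
    cf_initial: float
    cf_final: float
    evaluations: int
    restarts: int
    seed: int
    at_bound: list[str] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "fitted": self.fitted,
            "cf_initial": self.cf_initial,
            "cf_final": self.cf_final,
            "evaluations": self.evaluations,
            "restarts": self.restarts,
            "seed": self.seed,
            "at_bound": self.at_bound,
            "bounds": {n: list(b) for n, b in self.bounds.items()},
        }


@dataclass
class StagedFitResult:
    stages: list[FitResult]
    final_params: dict[str, float]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stages": [s.to_dict() for s in self.stages],
                    "final_params": self.final_params,
                },
                indent=1,
            )
        )

    def comparison_table(self, registry: ParameterRegistry) -> pd.DataFrame:
        """Nominal-vs-fitted table across all stages."""
        rows = []
        for st in self.stages:
            for name, value in st.fitted.items():
                rows.append(
                    (
                        st.stage,
                        name,
                        registry[name].nominal,
                        value,
                        registry[name].units,
                    )
                )
        return pd.DataFrame(
            rows, columns=["stage", "parameter", "nominal", "fitted", "units"]
        )


def _objective(model, dataset, protocol, y_exp, frozen, free_params, bounds):
    lo = np.array([bounds[n].lo_abs for n in free_params])
    up = np.array([bounds[n].up_abs for n in free_params])
    span = up - lo

    def unscale(x01: np.ndarray) -> dict[str, float]:
        vals = lo + x01 * span
        return dict(zip(free_params, map(float, vals)))

    failures = {"count": 0}

    def fun(x01: np.ndarray) -> float:
        params = dict(frozen)
        params.update(unscale(x01))
        try:
            resp = simulate_steady_state(model, params, protocol)
        except SimulationError:
            failures["count"] += 1
            return 1e6
        return cost_function(y_exp, resp.values)

    return fun, unscale, lo, up, span, failures


def fit_stage(
    model: Model,
    dataset: SteadyStateDataset,
    free_params: list[str],
    frozen_values: Mapping[str, float],
    bounds: Mapping[str, Bound],
    config: OptimizerConfig,
    stage: str = "base",
    protocol: Optional[StimulusProtocol] = None,
    initial: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """CMA-ES minimization of CF over ``free_params`` inside their bounds.

    Everything in ``frozen_values`` stays fixed.  The best-ever candidate
    is reported, never the last; reported values are strictly inside
    their bounds.  ``initial`` overrides the start values (defaults to
    the frozen/nominal vector).
    """
    if not free_params:
        raise ValueError("free_params must be nonempty")
    protocol = protocol or dataset.protocol
    mean = dataset.cohort_mean()
    levels = [k for k in range(protocol.n_levels) if k in mean.columns]
    if not levels:
        raise ValueError("dataset has no observations at the protocol's levels")
    y_exp = mean.reindex(index=list(model.variables.names))[levels]

    frozen = dict(model.registry.nominal_values())
    frozen.update(frozen_values)
    overlap = set(free_params) & set(frozen_values)
    if overlap:
        raise ValueError(f"free parameters also frozen: {sorted(overlap)}")

    fun, unscale, lo, up, span, failures = _objective(
        model, dataset, protocol, y_exp, frozen, free_params, bounds
    )
    start = {n: frozen[n] for n in free_params}
    if initial:
        start.update({n: initial[n] for n in initial if n in start})
    x0 = np.clip((np.array([start[n] for n in free_params]) - lo) / span, 0.0, 1.0)

    n = len(free_params)
    popsize = config.pop_size or default_popsize(n)
    max_iter = config.max_iter or 100 * n * n

    cf_initial = fun(x0)
    best_x, best_f = x0.copy(), cf_initial
    evals = 1
    restarts_used = 0
    for r in range(config.max_restart + 1):
        sigma = config.sigma0 * RESTART_SIGMA_DECAY**r
        rng = np.random.default_rng([int(config.seed) % 2**31, r])
        res = minimize_cmaes(
            fun,
            best_x,
            sigma,
            np.zeros(n),
            np.ones(n),
            popsize=popsize,
            max_iter=max_iter,
            max_fevals=config.max_fun_eval,
            tol_fun=config.tol_fun,
            tol_x=config.tol_x,
            rng=rng,
        )
        evals += res.nfev
        restarts_used = r
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x.copy()
        if best_f <= config.tol_fun:
            break
    if failures["count"] > 0 and best_f >= 1e6:
        raise SimulationError(
            f"stage {stage!r}: every candidate simulation failed "
            f"({failures['count']} failures)"
        )

    # report strictly inside bounds; flag near-bound parameters
    eps_in = 1e-12
    x_rep = np.clip(best_x, eps_in, 1.0 - eps_in)
    fitted = unscale(x_rep)
    at_bound = [
        name
        for name, x in zip(free_params, best_x)
        if x < 1e-6 or x > 1.0 - 1e-6
    ]
    return FitResult(
        stage=stage,
        fitted=fitted,
        cf_initial=float(cf_initial),
        cf_final=float(min(best_f, cf_initial)),
        evaluations=evals,
        restarts=restarts_used,
        seed=int(config.seed),
        at_bound=at_bound,
        bounds={n_: (bounds[n_].lo_abs, bounds[n_].up_abs) for n_ in free_params},
    )


def run_three_stage_fit(
    model: Model,
    dataset: SteadyStateDataset,
    plan: SelectionPlan,
    bound_overrides: Optional[Mapping[str, tuple[float, float]]] = None,
    config: Optional[OptimizerConfig] = None,
    protocol: Optional[StimulusProtocol] = None,
) -> StagedFitResult:
    """Base -> specific -> stimulus-related fitting with freeze semantics.

    Each stage freezes the standardized covariates plus every value
    fitted by earlier stages; the final vector merges standardized, base,
    specific and stimulus values over the nominals.  Empty stages are
    skipped (a plan with only a base set degenerates to a single fit).
    """
    if config is None:
        raise ValueError("an OptimizerConfig with a seed is required")
    stage_sets = plan.stage_sets()
    frozen: dict[str, float] = dict(plan.standardized)
    results: list[FitResult] = []
    for idx, stage in enumerate(STAGE_ORDER):
        free = stage_sets[stage]
        if not free:
            continue
        bounds = build_bounds(free, model.registry, bound_overrides)
        stage_seed = int(np.random.SeedSequence([int(config.seed), idx]).generate_state(1)[0] % 2**31)
        stage_cfg = OptimizerConfig(
            seed=stage_seed,
            tol_fun=config.tol_fun,
            tol_x=config.tol_x,
            max_iter=config.max_iter,
            max_fun_eval=config.max_fun_eval,
            max_restart=config.max_restart,
            pop_size=config.pop_size,
            sigma0=config.sigma0,
        )
        res = fit_stage(
            model,
            dataset,
            free,
            frozen,
            bounds,
            stage_cfg,
            stage=stage,
            protocol=protocol,
        )
        results.append(res)
        frozen.update(res.fitted)
    final = dict(model.registry.nominal_values())
    final.update(frozen)
    return StagedFitResult(stages=results, final_params=final)
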