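"""Parameter classification: subset selection and sensitivity ranking.

Two complementary screens over a grid of stimulus levels ``k`` and signed
parameter perturbations ``h_l``:

**Subset selection** (identifiability as a group).  For each (level,
variation) cell the residual Jacobian ``J[i, j] = d r_i / d u_j`` (with
``r_i = y_exp_i - y_sim_i``) is decomposed by SVD; the numerical rank
``rho`` is the number of normalized singular values ``sigma_p / sigma_1``
above a tolerance ``epsilon``; pivoted QR of the transposed leading right
singular vectors orders the parameters by how well-conditioned their
joint estimation is.  The parameter at pivot position ``p`` is assigned
the normalized singular value at that position; scores are aggregated by
root-mean-square over levels (``Z_jl``), then variations (``Z_j``), and
ranked descending.

**Sensitivity analysis** (sensitivity individually).  The steady-state
relative sensitivity is

    ``s_ijlk = |Y_ik((1 + h_l) u_j) - Y_ik(u_n)| / |Y_ik(u_n)| * |1/h_l|``

(one parameter perturbed at a time, the weighting ``1/|h_l|`` giving more
importance to small perturbations).  RMS over variations gives
``s_ijk``; normalizing per (variable, level) by the maximum over
parameters, weighting by the nominal-model error share ``P_ik`` and
taking RMS over levels gives ``s_ij``; one more weighted RMS over
variables with weights ``P_i`` gives the total sensitivity ``s_j``.  The
error weights are normalized shares of the nominal model's relative
prediction error, so screening emphasises exactly the (variable, level)
cells the subsequent fit must repair, and they sum to one by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import linalg

from .cohort import SteadyStateDataset
from .model import Model, SimulationError, StimulusProtocol, simulate_steady_state

logger = logging.getLogger(__name__)

#: default rank tolerance: sqrt of the optimizer's function-evaluation
#: termination tolerance (1e-12)
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class PerturbationGrid:
    """Signed fractional perturbations and the stimulus levels screened.

    The five-point uniform +/-5% grid is represented by its four nonzero
    points; the nominal (h = 0) is the implicit reference of every
    difference quotient and cannot itself enter them.
    """

    h: tuple[float, ...] = (-0.05, -0.025, 0.025, 0.05)
    levels: Optional[tuple[int, ...]] = None  # 0-based; None = all

    def __post_init__(self) -> None:
        if any(x == 0 for x in self.h):
            raise ValueError("h must not contain 0 (nominal is the reference)")
        if any(abs(x) > 1 for x in self.h):
            raise ValueError("|h| must be <= 1")
        if not (any(x > 0 for x in self.h) and any(x < 0 for x in self.h)):
            raise ValueError("h needs at least one positive and one negative entry")


@dataclass
class ScreeningResult:
    """All intermediates of both screens, consistently indexed.

    Tensor axes: ``i`` variable, ``j`` parameter, ``l`` variation,
    ``k`` stimulus level, in the orders given by ``variables``,
    ``candidates``, ``h`` and ``levels``.
    """

    candidates: list[str]
    variables: list[str]
    levels: list[int]
    h: list[float]
    epsilon: float
    # subset selection
    Z_jkl: np.ndarray  # (J, K, L)
    Z_jl: np.ndarray  # (J, L)
    Z_j: np.ndarray  # (J,)
    rho: dict[tuple[int, int], int]  # (k, l) -> numerical rank
    orderings: dict[tuple[int, int], list[str]]  # (k, l) -> pivot order
    # sensitivities
    s_ijlk: np.ndarray  # (I, J, L, K)
    s_ijk: np.ndarray  # (I, J, K)
    s_ij: np.ndarray  # (I, J)
    s_j: np.ndarray  # (J,)
    # error weights
    P_ik: np.ndarray  # (I, K)
    P_i: np.ndarray  # (I,)
    E_ik: np.ndarray  # (I, K)
    E_iT: np.ndarray  # (I,)
    E_i: np.ndarray  # (I,)
    E_T: float = 0.0
    param_subsystems: dict[str, str] = field(default_factory=dict)

    def subset_ranking(self) -> list[tuple[str, float]]:
        """Candidates with their Z_j score, descending (stable ties)."""
        order = np.argsort(-self.Z_j, kind="stable")
        return [(self.candidates[j], float(self.Z_j[j])) for j in order]

    def total_ranking(self) -> list[tuple[str, float]]:
        """Candidates with their total sensitivity s_j, descending."""
        order = np.argsort(-self.s_j, kind="stable")
        return [(self.candidates[j], float(self.s_j[j])) for j in order]

    def variable_ranking(self, variable: str) -> list[tuple[str, float]]:
        i = self.variables.index(variable)
        order = np.argsort(-self.s_ij[i], kind="stable")
        return [(self.candidates[j], float(self.s_ij[i, j])) for j in order]

    def to_json(self, path) -> None:
        payload = {
            "candidates": self.candidates,
            "variables": self.variables,
            "levels": self.levels,
            "h": self.h,
            "epsilon": self.epsilon,
            "Z_j": dict(zip(self.candidates, map(float, self.Z_j))),
            "s_j": dict(zip(self.candidates, map(float, self.s_j))),
            "Z_jl": self.Z_jl.tolist(),
            "Z_jkl": self.Z_jkl.tolist(),
            "s_ijlk": self.s_ijlk.tolist(),
            "s_ijk": self.s_ijk.tolist(),
            "s_ij": self.s_ij.tolist(),
            "P_ik": self.P_ik.tolist(),
            "P_i": self.P_i.tolist(),
            "E_ik": self.E_ik.tolist(),
            "E_iT": self.E_iT.tolist(),
            "E_i": self.E_i.tolist(),
            "E_T": self.E_T,
            "rho": {f"{k},{l}": v for (k, l), v in self.rho.items()},
            "orderings": {f"{k},{l}": v for (k, l), v in self.orderings.items()},
            "param_subsystems": self.param_subsystems,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def rankings_frame(self) -> pd.DataFrame:
        """Tidy (parameter, score, rank) table for both rankings."""
        rows = []
        for rank, (name, score) in enumerate(self.subset_ranking(), start=1):
            rows.append(("subset_selection", name, score, rank))
        for rank, (name, score) in enumerate(self.total_ranking(), start=1):
            rows.append(("total_sensitivity", name, score, rank))
        return pd.DataFrame(rows, columns=["ranking", "parameter", "score", "rank"])


def _single_level_protocol(protocol: StimulusProtocol, k: int) -> StimulusProtocol:
    return StimulusProtocol(
        (protocol.levels[k],), protocol.step_duration, protocol.settle_window
    )


def _simulate_level(
    model: Model, params: Mapping[str, float], protocol: StimulusProtocol, k: int
) -> np.ndarray:
    resp = simulate_steady_state(model, params, _single_level_protocol(protocol, k))
    return resp.values[0].to_numpy()


def residual_jacobian(
    model: Model,
    y_exp_k: np.ndarray,
    params: Mapping[str, float],
    protocol: StimulusProtocol,
    level: int,
    variation: float = 0.0,
    candidates: Optional[list[str]] = None,
    fd_step: float = 1e-6,
) -> np.ndarray:
    """Forward-difference Jacobian of the residual at one (level, variation).

    ``y_exp_k`` is the cohort-mean observation per variable at this level.
    All candidate parameters sit at their variation values ``(1 +
    variation) u_n``; entry (i, j) is ``d(y_exp_i - y_sim_i)/d u_j``.  The
    absolute step for parameter j is ``fd_step * |u_j|`` with floor 1e-9.
    """
    if candidates is None:
        candidates = model.registry.candidates()
    base = dict(params)
    for name in candidates:
        base[name] = params[name] * (1.0 + variation)
    y0 = _simulate_level(model, base, protocol, level)
    n_var = len(model.variables.names)
    jac = np.empty((n_var, len(candidates)))
    for j, name in enumerate(candidates):
        step = max(fd_step * abs(base[name]), 1e-9)
        pert = dict(base)
        pert[name] = base[name] + step
        try:
            y1 = _simulate_level(model, pert, protocol, level)
        except SimulationError as exc:
            raise SimulationError(
                f"perturbed simulation failed for {name!r} (step {step:g}): {exc}"
            ) from exc
        # r = y_exp - y_sim, so dr/du = -dy_sim/du
        jac[:, j] = -(y1 - y0) / step
    if not np.all(np.isfinite(jac)):
        raise SimulationError("non-finite entries in residual Jacobian")
    # y_exp enters r but is constant in u; kept in the signature for the
    # record (provenance) and future residual-weighted variants
    _ = y_exp_k
    return jac


def subset_selection_rank(
    jacobians: Mapping[tuple[int, int], np.ndarray],
    candidates: list[str],
    levels: list[int],
    h: list[float],
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict, dict]:
    """SVD rank + pivoted-QR ordering per (level, variation) cell.

    Returns ``(Z_jkl, Z_jl, Z_j, rho, orderings)``.  In each cell the
    parameter at pivot position p receives the normalized singular value
    ``sigma_p / sigma_1`` (0 where p exceeds the number of singular
    values); parameters beyond the numerical rank thereby receive values
    below ``epsilon`` by construction.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    J = len(candidates)
    K, L = len(levels), len(h)
    Z_jkl = np.zeros((J, K, L))
    rho: dict[tuple[int, int], int] = {}
    orderings: dict[tuple[int, int], list[str]] = {}
    for ki, k in enumerate(levels):
        for li in range(L):
            jac = jacobians[(k, li)]
            U, sv, Vt = np.linalg.svd(jac, full_matrices=False)
            if sv[0] <= 0:
                raise ValueError(
                    f"all-zero Jacobian at level {k + 1}, variation {h[li]}: "
                    "no identifiable parameter"
                )
            sv_norm = sv / sv[0]
            r = int(np.sum(sv_norm > epsilon))
            rho[(k, li)] = r
            V_r = Vt[:r, :]  # rows of Vt = leading right singular vectors^T
            _, _, perm = linalg.qr(V_r, pivoting=True, mode="economic")
            orderings[(k, li)] = [candidates[p] for p in perm]
            for pos, p in enumerate(perm):
                Z_jkl[p, ki, li] = sv_norm[pos] if pos < len(sv_norm) else 0.0
    Z_jl = np.sqrt(np.mean(Z_jkl**2, axis=1))  # RMS over levels
    Z_j = np.sqrt(np.mean(Z_jl**2, axis=1))  # then over variations
    return Z_jkl, Z_jl, Z_j, rho, orderings


def relative_sensitivity_tensor(
    model: Model,
    params: Mapping[str, float],
    protocol: StimulusProtocol,
    grid: PerturbationGrid,
    candidates: Optional[list[str]] = None,
    y_nominal: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Steady-state relative sensitivities ``s_ijlk`` (I, J, L, K).

    One parameter is perturbed at a time with all others at their nominal
    (reference) values.  Raises when any reference |Y| falls below 1e-12.
    """
    if candidates is None:
        candidates = model.registry.candidates()
    levels = list(grid.levels) if grid.levels is not None else list(range(protocol.n_levels))
    var_names = list(model.variables.names)
    I, J, L, K = len(var_names), len(candidates), len(grid.h), len(levels)
    if y_nominal is None:
        y_nominal = np.column_stack(
            [_simulate_level(model, params, protocol, k) for k in levels]
        )
    degenerate = [
        (var_names[i], levels[k] + 1)
        for i in range(I)
        for k in range(K)
        if abs(y_nominal[i, k]) < 1e-12
    ]
    if degenerate:
        raise ValueError(f"reference steady state ~0 for (variable, level): {degenerate}")
    s = np.empty((I, J, L, K))
    for j, name in enumerate(candidates):
        for li, hl in enumerate(grid.h):
            pert = dict(params)
            pert[name] = params[name] * (1.0 + hl)
            for ki, k in enumerate(levels):
                y1 = _simulate_level(model, pert, protocol, k)
                dy = np.abs(y1 - y_nominal[:, ki]) / np.abs(y_nominal[:, ki])
                s[:, j, li, ki] = dy / abs(hl)
    return s


def error_weights(
    y_exp: np.ndarray, y_sim: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Error shares of the nominal model: ``(E_ik, E_iT, P_ik, E_i, P_i, E_T)``.

    ``E_ik`` is the absolute relative error per (variable, level), ``E_i``
    the mean squared relative error per variable; the shares ``P_ik`` and
    ``P_i`` sum to one over levels resp. variables whenever the totals are
    nonzero.
    """
    if np.any(y_exp == 0):
        raise ValueError("experimental values must be nonzero for relative errors")
    K = y_exp.shape[1]
    I = y_exp.shape[0]
    rel = (y_exp - y_sim) / y_exp
    E_ik = np.abs(rel)
    E_iT = E_ik.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P_ik = E_ik / (K * E_iT[:, None])
    P_ik = np.where(E_iT[:, None] > 0, P_ik, 1.0 / K)
    E_i = (rel**2).mean(axis=1)
    E_T = float(E_i.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        P_i = E_i / (I * E_T)
    if E_T == 0:
        P_i = np.full(I, 1.0 / I)
    return E_ik, E_iT, P_ik, E_i, P_i, E_T


def aggregate_sensitivities(
    s_ijlk: np.ndarray, P_ik: np.ndarray, P_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse the sensitivity tensor: ``(s_ijk, s_ij, s_j)``.

    ``s_ijk`` is the RMS over variations; ``s_ij`` the error-weighted RMS
    over levels of the per-(variable, level)-normalized ``s_ijk``;
    ``s_j`` the error-weighted RMS over variables of the per-variable-
    normalized ``s_ij``.  (variable, level) cells where every parameter
    has zero sensitivity are excluded with a warning.
    """
    s_ijk = np.sqrt(np.mean(s_ijlk**2, axis=2))  # over variations l
    max_ik = s_ijk.max(axis=1)  # (I, K)
    dead = max_ik == 0
    if np.any(dead):
        logger.warning(
            "excluding %d (variable, level) cells with all-zero sensitivity",
            int(dead.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        norm_ijk = s_ijk / max_ik[:, None, :]
    norm_ijk = np.where(dead[:, None, :], 0.0, norm_ijk)
    weighted = P_ik[:, None, :] * norm_ijk
    live_K = (~dead).sum(axis=1)  # levels contributing per variable
    live_K = np.maximum(live_K, 1)
    s_ij = np.sqrt((weighted**2).sum(axis=2) / live_K[:, None])

    max_i = s_ij.max(axis=1)  # (I,)
    dead_i = max_i == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        norm_ij = s_ij / max_i[:, None]
    norm_ij = np.where(dead_i[:, None], 0.0, norm_ij)
    weighted_i = P_i[:, None] * norm_ij
    live_I = max(int((~dead_i).sum()), 1)
    s_j = np.sqrt((weighted_i**2).sum(axis=0) / live_I)
    return s_ijk, s_ij, s_j


def screen(
    model: Model,
    dataset: SteadyStateDataset,
    params: Optional[Mapping[str, float]] = None,
    protocol: Optional[StimulusProtocol] = None,
    grid: PerturbationGrid = PerturbationGrid(),
    epsilon: float = DEFAULT_EPSILON,
    fd_step: float = 1e-6,
) -> ScreeningResult:
    """Run both screens end to end against a dataset's cohort means."""
    from .model import complete_params

    protocol = protocol or dataset.protocol
    full = complete_params(model, params)
    candidates = model.registry.candidates()
    levels = list(grid.levels) if grid.levels is not None else list(range(protocol.n_levels))
    var_names = list(model.variables.names)

    mean = dataset.cohort_mean()
    missing = [k for k in levels if k not in mean.columns]
    if missing:
        raise ValueError(f"dataset has no observations at levels {missing}")
    y_exp = mean.reindex(index=var_names)[levels].to_numpy()

    y_nom = np.column_stack([_simulate_level(model, full, protocol, k) for k in levels])

    jacobians = {
        (k, li): residual_jacobian(
            model, y_exp[:, ki], full, protocol, k, hl, candidates, fd_step
        )
        for ki, k in enumerate(levels)
        for li, hl in enumerate(grid.h)
    }
    Z_jkl, Z_jl, Z_j, rho, orderings = subset_selection_rank(
        jacobians, candidates, levels, list(grid.h), epsilon
    )

    s_ijlk = relative_sensitivity_tensor(model, full, protocol, grid, candidates, y_nom)
    E_ik, E_iT, P_ik, E_i, P_i, E_T = error_weights(y_exp, y_nom)
    s_ijk, s_ij, s_j = aggregate_sensitivities(s_ijlk, P_ik, P_i)

    return ScreeningResult(
        candidates=candidates,
        variables=var_names,
        levels=levels,
        h=list(grid.h),
        epsilon=epsilon,
        Z_jkl=Z_jkl,
        Z_jl=Z_jl,
        Z_j=Z_j,
        rho=rho,
        orderings=orderings,
        s_ijlk=s_ijlk,
        s_ijk=s_ijk,
        s_ij=s_ij,
        s_j=s_j,
        P_ik=P_ik,
        P_i=P_i,
        E_ik=E_ik,
        E_iT=E_iT,
        E_i=E_i,
        E_T=E_T,
        param_subsystems={n: model.registry[n].subsystem for n in candidates},
    )
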