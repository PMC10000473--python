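"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES with rank-one and rank-mu covariance
updates, cumulative step-size adaptation, and box constraints handled by
repair: candidates sampled outside the box are clipped to it before
evaluation and the repaired point is fed back to the update, so every
evaluated (and reported) point is feasible.

Strategy constants follow the standard tutorial settings.  Termination:
function-evaluation and iteration budgets, stagnation of the best
function value below ``tol_fun`` over a trailing window, and step-size
collapse below ``tol_x`` (expressed relative to the initial step size, so
chained restarts with shrinking initial steps can keep refining).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np


def default_popsize(n: int) -> int:
    """Canonical population size ``4 + floor(3 ln n)`` (>= 4)."""
    return 4 + int(math.floor(3 * math.log(max(n, 1))))


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    nfev: int
    nit: int
    stop: str


def minimize_cmaes(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    lower: np.ndarray,
    upper: np.ndarray,
    popsize: Optional[int] = None,
    max_iter: Optional[int] = None,
    max_fevals: int = 500,
    tol_fun: float = 1e-12,
    tol_x: float = 1e-3,
    rng: Optional[np.random.Generator] = None,
) -> CMAResult:
    """Minimize ``fun`` over the box ``[lower, upper]`` starting at ``x0``.

    ``tol_x`` terminates when the largest coordinate standard deviation of
    the search distribution falls below ``tol_x * sigma0``.
    """
    rng = rng or np.random.default_rng()
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = popsize if popsize is not None else default_popsize(n)
    lam = max(lam, 4)
    if max_iter is None:
        max_iter = 100 * n * n
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    m = np.clip(x0, lower, upper)
    sigma = sigma0
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x = m.copy()
    best_f = math.inf
    nfev = 0
    it = 0
    hist: list[float] = []
    hist_len = 10 + int(math.ceil(30 * n / lam))
    stop = "max_fevals"

    while nfev < max_fevals and it < max_iter:
        it += 1
        # eigendecomposition each iteration (dimensions here are small)
        C = (C + C.T) / 2
        evals, B = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        D = np.sqrt(evals)
        if D.max() / D.min() > 1e7:
            stop = "condition"
            break
        invsqrtC = B @ np.diag(1.0 / D) @ B.T

        k = min(lam, max_fevals - nfev)
        Z = rng.standard_normal((lam, n))
        X_raw = m + sigma * (Z @ (B * D).T)
        X = np.clip(X_raw, lower, upper)
        f_vals = np.full(lam, math.inf)
        for i in range(k):
            f_vals[i] = fun(X[i])
            nfev += 1
        order = np.argsort(f_vals, kind="stable")
        if f_vals[order[0]] < best_f:
            best_f = float(f_vals[order[0]])
            best_x = X[order[0]].copy()
        if k < lam:
            # budget exhausted mid-generation: best-ever already recorded
            stop = "max_fevals"
            break
        hist.append(float(f_vals[order[0]]))
        if len(hist) > hist_len:
            hist.pop(0)

        sel = X[order[:mu]]  # repaired points drive the update
        m_old = m
        m = w @ sel
        y = (m - m_old) / sigma
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mueff) * (invsqrtC @ y)
        hsig = (
            np.linalg.norm(ps) / math.sqrt(1 - (1 - cs) ** (2 * it)) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + (hsig * math.sqrt(cc * (2 - cc) * mueff)) * y
        artmp = (sel - m_old) / sigma
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
            + cmu * (artmp.T * w) @ artmp
        )
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))

        if sigma * math.sqrt(float(np.max(np.diag(C)))) < tol_x * sigma0:
            stop = "tol_x"
            break
        if len(hist) >= hist_len and max(hist) - min(hist) < tol_fun:
            stop = "tol_fun"
            break
    else:
        stop = "max_iter" if it >= max_iter else "max_fevals"

    return CMAResult(x=best_x, fun=best_f, nfev=nfev, nit=it, stop=stop)
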