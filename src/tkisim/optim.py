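"""Derivative-free optimizers for calibration: CMA-ES and a Nelder–Mead fallback.

The CMA-ES here is the standard (mu/mu_w, lambda) evolution strategy with
cumulative step-size adaptation and rank-one plus rank-mu covariance
updates.  It is deliberately compact: box constraints are enforced by
projecting samples onto the feasible box before evaluation, which is
adequate for the low-dimensional, smooth calibration tasks this package
runs.  Reproducibility: the full sampling stream derives from the given
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = ["OptimizerResult", "cmaes_minimize", "nelder_mead_minimize"]


@dataclass
class OptimizerResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    trace: np.ndarray  # best-so-far objective after each generation/iteration
    converged: bool


def cmaes_minimize(
    objective: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    bounds: Sequence[tuple[float, float]],
    max_evaluations: int = 4000,
    popsize: int | None = None,
    ftol: float = 1e-12,
    seed: int | None = None,
) -> OptimizerResult:
    """Minimize ``objective`` over a box with CMA-ES.

    ``sigma0`` is the initial global step size on the (already transformed)
    parameter scale; a value near a quarter of the typical box width works
    well.
    """
    rng = np.random.default_rng(seed)
    x_mean = np.array(x0, dtype=float)
    n = len(x_mean)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo) or not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite with hi > lo")
    x_mean = np.clip(x_mean, lo, hi)

    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    raw = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w = raw / raw.sum()
    mu_eff = 1.0 / np.sum(w**2)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    sigma = float(sigma0)
    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    best_x, best_f = x_mean.copy(), np.inf
    trace = []
    evals = 0
    converged = False

    while evals < max_evaluations:
        try:
            A = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            C = np.eye(n)
            A = np.eye(n)
        z = rng.standard_normal((lam, n))
        y = z @ A.T
        xs = np.clip(x_mean + sigma * y, lo, hi)
        fs = np.array([objective(x) for x in xs])
        evals += lam
        if not np.any(np.isfinite(fs)):
            if evals == lam:
                raise ValueError("objective non-finite at all initial points")
            break
        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs[order[0]].copy()
        trace.append(best_f)

        # effective steps after projection, so the moments match what was kept
        y_sel = (xs[order[:mu]] - x_mean) / sigma
        y_w = w @ y_sel
        x_mean = x_mean + sigma * y_w

        C_inv_sqrt = np.linalg.inv(A)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (C_inv_sqrt @ y_w)
        h_sig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (evals // lam)))
            < (1.4 + 2 / (n + 1)) * chi_n
        )
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (not h_sig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= float(np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1)))

        # best-so-far can stall for many generations in curved valleys;
        # only stop on a long flat stretch or a collapsed search distribution
        stall = max(60, 30 * n)
        if len(trace) > stall and abs(trace[-stall] - trace[-1]) < ftol * (
            1 + abs(trace[-1])
        ):
            converged = True
            break
        if sigma * np.sqrt(np.max(np.diag(C))) < 1e-14 * (hi - lo).max():
            converged = True
            break

    return OptimizerResult(
        x=best_x, fun=best_f, n_evaluations=evals,
        trace=np.minimum.accumulate(np.array(trace)), converged=converged,
    )


def nelder_mead_minimize(
    objective: Callable[[np.ndarray], float],
    x0: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    max_evaluations: int = 4000,
) -> OptimizerResult:
    """Nelder–Mead fallback for tiny tasks, with the same result contract."""
    trace: list[float] = []
    best = [np.inf]

    def wrapped(x):
        f = objective(np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds]))
        best[0] = min(best[0], f)
        trace.append(best[0])
        return f

    res = minimize(
        wrapped, np.asarray(x0, dtype=float), method="Nelder-Mead",
        bounds=bounds, options={"maxfev": max_evaluations, "xatol": 1e-10,
                                "fatol": 1e-12},
    )
    return OptimizerResult(
        x=np.asarray(res.x), fun=float(res.fun), n_evaluations=res.nfev,
        trace=np.array(trace), converged=bool(res.success),
    )
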