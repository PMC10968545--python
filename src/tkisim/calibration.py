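"""Step-wise calibration of model parameters by objective-function minimization.

A :class:`CalibrationTask` names the free parameters (bounds, log or linear
search scale), a weighted sum-of-squares objective over named observables,
and optimizer settings.  Tasks are meant to be chained (PK first, then
tumor/population parameters), each step freezing the previous step's
result, following a step-wise strategy for heterogeneous constraints.
CMA-ES is the default optimizer; Nelder–Mead is available for tiny smooth
tasks.

PK residuals are computed on log-concentrations (profiles span decades);
volume/outcome residuals on the linear scale — the caller chooses via the
observable weights and the ``log_residuals`` flag of
:func:`sum_of_squares_objective`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from tkisim.optim import OptimizerResult, cmaes_minimize, nelder_mead_minimize

__all__ = [
    "FreeParameter",
    "CalibrationTask",
    "CalibrationResult",
    "fit",
    "sum_of_squares_objective",
    "visual_predictive_check",
]


@dataclass(frozen=True)
class FreeParameter:
    """One calibrated parameter: bounds and search-scale transform."""

    name: str
    lower: float
    upper: float
    transform: Literal["linear", "log"] = "linear"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.transform == "log" and self.lower <= 0:
            raise ValueError("log-scale parameters need positive bounds")

    def to_internal(self, value: float) -> float:
        return float(np.log(value)) if self.transform == "log" else float(value)

    def from_internal(self, value: float) -> float:
        return float(np.exp(value)) if self.transform == "log" else float(value)

    def internal_bounds(self) -> tuple[float, float]:
        return self.to_internal(self.lower), self.to_internal(self.upper)


@dataclass
class CalibrationTask:
    """Objective + free parameters + optimizer settings for one step."""

    parameters: Sequence[FreeParameter]
    objective: Callable[[dict[str, float]], float]
    step: str = "step"
    x0: dict[str, float] | None = None
    optimizer: Literal["cmaes", "nelder-mead"] = "cmaes"
    max_evaluations: int = 4000
    popsize: int | None = None
    sigma0_fraction: float = 0.25  # of the internal box width
    seed: int | None = None


@dataclass
class CalibrationResult:
    step: str
    parameters: dict[str, float]
    objective: float
    n_evaluations: int
    trace: np.ndarray

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "parameters": self.parameters,
            "objective": self.objective,
            "n_evaluations": self.n_evaluations,
        }


def _vector_objective(task: CalibrationTask):
    params = list(task.parameters)

    def f(x: np.ndarray) -> float:
        values = {p.name: p.from_internal(xi) for p, xi in zip(params, x)}
        try:
            val = float(task.objective(values))
        except (FloatingPointError, OverflowError, ValueError):
            return np.inf
        return val if np.isfinite(val) else np.inf

    return f


def fit(task: CalibrationTask) -> CalibrationResult:
    """Minimize the task objective; returns best parameters and a monotone trace."""
    params = list(task.parameters)
    bounds = [p.internal_bounds() for p in params]
    if task.x0 is not None:
        x0 = np.array([p.to_internal(task.x0[p.name]) for p in params])
    else:
        x0 = np.array([0.5 * (lo + hi) for lo, hi in bounds])
    f = _vector_objective(task)
    if not np.isfinite(f(x0)):
        # scan the box diagonal for a finite start before giving up
        candidates = [
            np.array([lo + frac * (hi - lo) for lo, hi in bounds])
            for frac in (0.25, 0.75, 0.1, 0.9)
        ]
        for cand in candidates:
            if np.isfinite(f(cand)):
                x0 = cand
                break
        else:
            raise ValueError("objective is non-finite at all initial points")

    if task.optimizer == "cmaes":
        width = max(hi - lo for lo, hi in bounds)
        result: OptimizerResult = cmaes_minimize(
            f, x0, sigma0=task.sigma0_fraction * width, bounds=bounds,
            max_evaluations=task.max_evaluations, popsize=task.popsize,
            seed=task.seed,
        )
    elif task.optimizer == "nelder-mead":
        result = nelder_mead_minimize(
            f, x0, bounds=bounds, max_evaluations=task.max_evaluations
        )
    else:
        raise ValueError(f"unknown optimizer {task.optimizer!r}")

    best = {p.name: p.from_internal(xi) for p, xi in zip(params, result.x)}
    return CalibrationResult(
        step=task.step, parameters=best, objective=result.fun,
        n_evaluations=result.n_evaluations, trace=result.trace,
    )


def sum_of_squares_objective(
    simulate: Callable[[dict[str, float]], np.ndarray],
    observed: np.ndarray,
    weights: np.ndarray | None = None,
    log_residuals: bool = False,
    floor: float = 1e-12,
) -> Callable[[dict[str, float]], float]:
    """Weighted SSE objective between a simulator output and observations.

    With ``log_residuals`` the residuals are differences of logarithms
    (appropriate for concentration profiles spanning decades); values are
    floored at ``floor`` before taking logs.
    """
    observed = np.asarray(observed, dtype=float)
    w = np.ones_like(observed) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")

    def objective(values: dict[str, float]) -> float:
        sim = np.asarray(simulate(values), dtype=float)
        if log_residuals:
            r = np.log(np.maximum(sim, floor)) - np.log(np.maximum(observed, floor))
        else:
            r = sim - observed
        return float(np.sum(w * r * r))

    return objective


def visual_predictive_check(
    simulated: np.ndarray,
    data: pd.DataFrame,
) -> dict:
    """Overlay simulated points on observed mean +/- sd bands.

    ``data`` needs columns ``time``, ``mean`` and ``sd``; ``simulated`` is
    the model output at the same time points.  Returns the overlay table and
    the fraction of simulated points inside the one-standard-deviation band.
    """
    for col in ("time", "mean", "sd"):
        if col not in data.columns:
            raise ValueError(f"data needs a {col!r} column")
    sim = np.asarray(simulated, dtype=float)
    if len(sim) != len(data):
        raise ValueError("simulated series and data must align")
    lo = data["mean"].to_numpy() - data["sd"].to_numpy()
    hi = data["mean"].to_numpy() + data["sd"].to_numpy()
    inside = (sim >= lo) & (sim <= hi)
    overlay = pd.DataFrame({
        "time": data["time"].to_numpy(),
        "observed_mean": data["mean"].to_numpy(),
        "observed_sd": data["sd"].to_numpy(),
        "simulated": sim,
        "inside_band": inside,
    })
    return {"overlay": overlay, "fraction_inside": float(inside.mean())}
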