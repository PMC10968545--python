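"""Synthetic-data generators for calibration and statistics tests.

Three fixture kinds, all seeded and reproducible:

* ``plasma_pk`` — noisy one-compartment oral concentration profiles with
  known ground-truth parameters (for parameter-recovery tests);
* ``event_times`` — Weibull or exponential event tables with administrative
  censoring (stand-ins for comparator time-to-progression tables);
* ``toy_population`` — a small virtual-population descriptor table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tkisim.population import PopulationSpec, population_table, sample_population

__all__ = [
    "one_compartment_oral",
    "plasma_pk_fixture",
    "event_times_fixture",
    "toy_population_fixture",
    "generate_fixtures",
]


def one_compartment_oral(
    t: np.ndarray, dose: float, f: float, ka: float, cl: float, v: float
) -> np.ndarray:
    """Closed-form oral one-compartment concentration C(t), mg/L."""
    t = np.asarray(t, dtype=float)
    ke = cl / v
    if abs(ka - ke) < 1e-12:
        return f * dose * ka * t * np.exp(-ka * t) / v
    return (
        f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    )


def plasma_pk_fixture(
    n_times: int = 12,
    t_max: float = 48.0,
    dose: float = 100.0,
    f: float = 0.8,
    ka: float = 1.0,
    cl: float = 5.0,
    v: float = 60.0,
    noise_cv: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy one-compartment profile with the ground truth in ``attrs``.

    The sampling grid is geometric (dense early, sparse late), mirroring how
    clinical PK studies cover the absorption phase; this keeps the
    absorption rate identifiable.
    """
    rng = np.random.default_rng(seed)
    t = t_max * np.geomspace(0.005, 1.0, n_times)
    c = one_compartment_oral(t, dose, f, ka, cl, v)
    noisy = c * np.exp(rng.normal(0.0, noise_cv, size=c.shape)) if noise_cv > 0 else c
    out = pd.DataFrame({"time": t, "concentration": noisy})
    out.attrs["truth"] = {"dose": dose, "f": f, "ka": ka, "cl": cl, "v": v}
    return out


def event_times_fixture(
    n: int = 100,
    shape: float = 1.0,
    scale: float = 10.0,
    censor_time: float = 24.0,
    extra_censor_fraction: float = 0.0,
    group: str = "sim",
    seed: int | None = None,
) -> pd.DataFrame:
    """Weibull(shape, scale) event table with administrative censoring.

    ``shape = 1`` gives the exponential with rate ``1/scale`` per month.
    A fraction of subjects can additionally be censored uniformly before
    their event (dropout-style).
    """
    rng = np.random.default_rng(seed)
    raw = scale * rng.weibull(shape, size=n)
    time = np.minimum(raw, censor_time)
    event = raw <= censor_time
    if extra_censor_fraction > 0:
        drop = rng.random(n) < extra_censor_fraction
        drop_time = rng.uniform(0, time, size=n)
        time = np.where(drop, drop_time, time)
        event = np.where(drop, False, event)
    return pd.DataFrame({"time": time, "event": event.astype(bool), "group": group})


def toy_population_fixture(n: int = 20, seed: int | None = None) -> pd.DataFrame:
    """Small descriptor table sampled from the default population spec."""
    spec = PopulationSpec(n_patients=n)
    return population_table(sample_population(spec, master_seed=seed or 0))


def generate_fixtures(kind: str, params: dict | None = None, seed: int | None = None):
    """Dispatch by fixture kind; unknown kinds raise."""
    params = dict(params or {})
    if kind == "plasma_pk":
        return plasma_pk_fixture(seed=seed, **params)
    if kind == "event_times":
        return event_times_fixture(seed=seed, **params)
    if kind == "toy_population":
        return toy_population_fixture(seed=seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")
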