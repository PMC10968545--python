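"""Survival statistics: KM curves, weighted log-rank, MaxCombo, similarity, effect model.

Event tables are tidy frames with columns ``time`` (months), ``event``
(1 = progression observed, 0 = censored) and ``group``.

The two-sample machinery implements the Fleming–Harrington G(rho, gamma)
weighted log-rank family with weight ``S(t-)^rho * (1 - S(t-))^gamma`` on
the left-continuous pooled Kaplan–Meier estimate; (0, 0) is the standard
log-rank.  MaxCombo takes the maximum absolute standardized statistic over a
weight set, with p-values either by permutation (exact for small tables) or
from the multivariate-normal null of the component statistics using their
estimated correlation.

Curve similarity follows a bootstrapped subsampling scheme: many subsamples,
each a tenth of the simulated population, are tested against the comparator;
the similarity ratio is the fraction of non-significant tests, declared
similar when it reaches the decision threshold (default 80%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

__all__ = [
    "SurvivalCurve",
    "ComparisonReport",
    "km_estimate",
    "km_median",
    "weighted_logrank",
    "maxcombo",
    "bootstrap_similarity",
    "effect_model",
    "DEFAULT_WEIGHT_SET",
]

DEFAULT_WEIGHT_SET: tuple[tuple[float, float], ...] = (
    (0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0),
)


def _validate_table(table: pd.DataFrame, n_groups: int | None = None) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in table.columns:
            raise ValueError(f"event table needs a {col!r} column")
    if (table["time"] < 0).any():
        raise ValueError("event times must be >= 0")
    if n_groups is not None:
        groups = table["group"].unique()
        if len(groups) != n_groups:
            raise ValueError(f"expected {n_groups} groups, found {len(groups)}")
        if (table.groupby("group").size() == 0).any():
            raise ValueError("every group needs at least one subject")
    return table


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step function with Greenwood variance."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t)

    def evaluate(self, t: np.ndarray | float) -> np.ndarray | float:
        """Right-continuous evaluation of S(t) (1 before the first event)."""
        if len(self.times) == 0:
            s = np.ones_like(np.asarray(t, dtype=float))
        else:
            idx = np.searchsorted(self.times, np.asarray(t), side="right") - 1
            s = np.where(idx < 0, 1.0, self.survival[np.maximum(idx, 0)])
        return float(s) if np.isscalar(t) else s


def km_estimate(table: pd.DataFrame) -> SurvivalCurve:
    """Kaplan–Meier curve of one sample (all groups pooled).

    The product-limit estimate and risk-set bookkeeping come from lifelines;
    the Greenwood variance is assembled from its event table.
    """
    _validate_table(table)
    if len(table) == 0:
        raise ValueError("empty event table")
    kmf = KaplanMeierFitter()
    kmf.fit(table["time"], event_observed=table["event"])
    et = kmf.event_table
    observed = et["observed"].to_numpy(dtype=float)
    at_risk = et["at_risk"].to_numpy(dtype=float)
    times = et.index.to_numpy(dtype=float)
    keep = observed > 0
    times, observed_k, at_risk_k = times[keep], observed[keep], at_risk[keep]
    surv = kmf.survival_function_["KM_estimate"].reindex(times).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood_terms = observed_k / (at_risk_k * (at_risk_k - observed_k))
    greenwood_terms[~np.isfinite(greenwood_terms)] = 0.0
    variance = surv**2 * np.cumsum(greenwood_terms)
    return SurvivalCurve(
        times=times, survival=surv, at_risk=at_risk_k, variance=variance
    )


def km_median(table: pd.DataFrame) -> float:
    """Median survival time (inf when the curve never reaches 0.5)."""
    curve = km_estimate(table)
    below = curve.survival <= 0.5
    return float(curve.times[below][0]) if below.any() else float("inf")


def _counting_arrays(time, event, group1):
    """Risk-set and event counts at the distinct pooled event times."""
    order = np.argsort(time, kind="stable")
    time, event, group1 = time[order], event[order], group1[order]
    event_times = np.unique(time[event])
    # at risk: subjects with time >= t
    n_at = np.searchsorted(time, event_times, side="left")
    n_risk = len(time) - n_at
    n1_risk = np.array([np.sum((time >= t) & group1) for t in event_times], dtype=float)
    d = np.array([np.sum((time == t) & event) for t in event_times], dtype=float)
    d1 = np.array(
        [np.sum((time == t) & event & group1) for t in event_times], dtype=float
    )
    return event_times, n_risk.astype(float), n1_risk, d, d1


def _pooled_km_left(event_times, n_risk, d):
    """Left-continuous pooled KM S(t-) at each event time."""
    factors = 1.0 - d / n_risk
    s_right = np.cumprod(factors)
    return np.concatenate([[1.0], s_right[:-1]])


def _fh_components(time, event, group1, weight_set):
    """Score U_j, variance V_jj and covariances for each FH weight."""
    event_times, n_risk, n1_risk, d, d1 = _counting_arrays(time, event, group1)
    if len(event_times) == 0:
        k = len(weight_set)
        return np.zeros(k), np.eye(k)
    s_minus = _pooled_km_left(event_times, n_risk, d)
    expected = d * n1_risk / n_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        var_t = (
            d * (n1_risk / n_risk) * (1.0 - n1_risk / n_risk)
            * (n_risk - d) / np.maximum(n_risk - 1.0, 1.0)
        )
    weights = np.array([
        s_minus**rho * (1.0 - s_minus)**gamma for rho, gamma in weight_set
    ])
    scores = weights @ (d1 - expected)
    cov = (weights * var_t) @ weights.T
    return scores, cov


def weighted_logrank(
    table: pd.DataFrame,
    rho: float = 0.0,
    gamma: float = 0.0,
    method: str = "normal",
    n_permutations: int = 2000,
    seed: int | None = None,
) -> dict[str, float]:
    """Fleming–Harrington G(rho, gamma) two-sample test.

    Returns ``statistic`` (standardized Z), ``p`` (two-sided) and the raw
    ``score``.  ``method`` is ``"normal"`` (asymptotic) or ``"permutation"``
    (group labels permuted, exact null for exchangeable censoring).
    """
    _validate_table(table, n_groups=2)
    groups = np.sort(table["group"].unique())
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=bool)
    group1 = (table["group"] == groups[1]).to_numpy()

    scores, cov = _fh_components(time, event, group1, [(rho, gamma)])
    score, var = scores[0], cov[0, 0]
    z = score / np.sqrt(var) if var > 0 else 0.0
    if method == "normal":
        p = 2.0 * sps.norm.sf(abs(z))
    elif method == "permutation":
        p = _permutation_p(
            time, event, group1, [(rho, gamma)], abs(z), n_permutations, seed,
            statistic="single",
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(z), "p": float(p), "score": float(score)}


def _standardized(scores, cov):
    sd = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    return scores / sd


def _perm_iter(n, n1, n_permutations, rng):
    """Yield group-1 masks: exhaustive when feasible, else random."""
    from math import comb

    if comb(n, n1) <= n_permutations:
        idx = np.arange(n)
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            yield mask
    else:
        for _ in range(n_permutations):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n1, replace=False)] = True
            yield mask


def _permutation_p(time, event, group1, weight_set, observed, n_permutations,
                   seed, statistic="max"):
    rng = np.random.default_rng(seed)
    n, n1 = len(time), int(group1.sum())
    count = total = 0
    for mask in _perm_iter(n, n1, n_permutations, rng):
        scores, cov = _fh_components(time, event, mask, weight_set)
        z = _standardized(scores, cov)
        stat = np.max(np.abs(z)) if statistic == "max" else abs(z[0])
        count += stat >= observed - 1e-12
        total += 1
    return count / total


def maxcombo(
    table: pd.DataFrame,
    weight_set: tuple[tuple[float, float], ...] = DEFAULT_WEIGHT_SET,
    method: str = "permutation",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """MaxCombo test: max |Z| over a Fleming–Harrington weight set.

    ``method="permutation"`` permutes group labels (exhaustive for small
    tables); ``method="mvn"`` integrates the multivariate-normal null over
    the estimated correlation of the component statistics.
    """
    _validate_table(table, n_groups=2)
    if len(weight_set) == 0:
        raise ValueError("weight_set must be non-empty")
    groups = np.sort(table["group"].unique())
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=bool)
    group1 = (table["group"] == groups[1]).to_numpy()

    scores, cov = _fh_components(time, event, group1, list(weight_set))
    z = _standardized(scores, cov)
    stat = float(np.max(np.abs(z)))

    if method == "permutation":
        p = _permutation_p(time, event, group1, list(weight_set), stat,
                           n_permutations, seed, statistic="max")
    elif method == "mvn":
        sd = np.sqrt(np.maximum(np.diag(cov), 1e-300))
        corr = cov / np.outer(sd, sd)
        corr = 0.5 * (corr + corr.T)
        corr += 1e-10 * np.eye(len(corr))
        k = len(corr)
        # orthant probability via Genz quasi-MC at reduced accuracy: 1e-4
        # absolute error is far below any alpha decision margin used here
        inside = sps.multivariate_normal.cdf(
            np.full(k, stat), mean=np.zeros(k), cov=corr, allow_singular=True,
            maxpts=20_000 * k, abseps=1e-4, releps=0.0,
            lower_limit=np.full(k, -stat),
        )
        p = float(np.clip(1.0 - inside, 0.0, 1.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    components = {
        f"z_rho{rho:g}_gamma{gamma:g}": float(zz)
        for (rho, gamma), zz in zip(weight_set, z)
    }
    return {"statistic": stat, "p": float(p), **components}


@dataclass
class ComparisonReport:
    """Bootstrapped similarity of a simulated curve to a comparator."""

    n_bootstrap: int
    subsample_fraction: float
    alpha: float
    similarity_ratio: float
    threshold: float
    similar: bool
    p_values: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_bootstrap": self.n_bootstrap,
            "subsample_fraction": self.subsample_fraction,
            "alpha": self.alpha,
            "similarity_ratio": self.similarity_ratio,
            "threshold": self.threshold,
            "similar": self.similar,
        }


def bootstrap_similarity(
    simulated: pd.DataFrame,
    comparator: pd.DataFrame,
    n_bootstrap: int = 5000,
    subsample_fraction: float = 0.1,
    alpha: float = 0.05,
    threshold: float = 0.80,
    weight_set: tuple[tuple[float, float], ...] = DEFAULT_WEIGHT_SET,
    seed: int | None = None,
) -> ComparisonReport:
    """Bootstrapped MaxCombo similarity of simulated vs comparator curves.

    Each replicate draws ``floor(n * subsample_fraction)`` simulated
    subjects without replacement and MaxCombo-tests them against the full
    comparator at level ``alpha`` (multivariate-normal p-values, adequate at
    the replicate sample sizes used here).  The similarity ratio is the
    fraction of non-significant replicates.
    """
    _validate_table(simulated)
    _validate_table(comparator)
    n_sub = int(len(simulated) * subsample_fraction)
    if n_sub < 2:
        raise ValueError("subsample smaller than 2; increase data or fraction")
    rng = np.random.default_rng(seed)
    comp = comparator[["time", "event"]].copy()
    comp["group"] = "comparator"
    sim_times = simulated["time"].to_numpy()
    sim_events = simulated["event"].to_numpy()
    p_values = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.choice(len(sim_times), size=n_sub, replace=False)
        sub = pd.DataFrame({
            "time": sim_times[idx], "event": sim_events[idx], "group": "simulated",
        })
        merged = pd.concat([sub, comp], ignore_index=True)
        p_values[b] = maxcombo(merged, weight_set=weight_set, method="mvn")["p"]
    ratio = float(np.mean(p_values > alpha))
    return ComparisonReport(
        n_bootstrap=n_bootstrap, subsample_fraction=subsample_fraction,
        alpha=alpha, similarity_ratio=ratio, threshold=threshold,
        similar=ratio >= threshold, p_values=p_values,
    )


def effect_model(
    outcomes_a: pd.DataFrame,
    outcomes_b: pd.DataFrame,
    horizon: float = 24.0,
) -> dict:
    """Paired per-patient benefit analysis of two arms on the same patients.

    Only patients progressing under BOTH drugs within the horizon enter the
    paired scatter; censored patients are tallied as non-progressors.
    Returns the paired table (``ttp_a``, ``ttp_b``, ``benefit`` = a - b),
    medians, the Pearson correlation and the 1-SD covariance-ellipse
    parameters (semi-axes and orientation).
    """
    a = outcomes_a.set_index("patient")
    b = outcomes_b.set_index("patient")
    if set(a.index) != set(b.index):
        raise ValueError("arms must contain the same patients (paired by id)")
    b = b.reindex(a.index)
    prog_a = a["event"].astype(bool) & (a["ttp_months"] <= horizon)
    prog_b = b["event"].astype(bool) & (b["ttp_months"] <= horizon)
    both = prog_a & prog_b
    paired = pd.DataFrame({
        "patient": a.index[both],
        "ttp_a": a.loc[both, "ttp_months"].to_numpy(),
        "ttp_b": b.loc[both, "ttp_months"].to_numpy(),
    })
    paired["benefit"] = paired["ttp_a"] - paired["ttp_b"]

    n = len(paired)
    if n >= 2 and paired["ttp_a"].std() > 0 and paired["ttp_b"].std() > 0:
        pearson = float(np.corrcoef(paired["ttp_a"], paired["ttp_b"])[0, 1])
    elif n >= 1:
        pearson = 1.0 if np.allclose(paired["ttp_a"], paired["ttp_b"]) else float("nan")
    else:
        pearson = float("nan")

    if n >= 2:
        cov = np.cov(paired["ttp_a"], paired["ttp_b"])
        eigval, eigvec = np.linalg.eigh(cov)
        # 1-SD ellipse: semi-axes sqrt(eigenvalues), orientation of the major axis
        major = int(np.argmax(eigval))
        angle = float(np.arctan2(eigvec[1, major], eigvec[0, major]))
        semi_axes = tuple(float(np.sqrt(max(v, 0.0))) for v in sorted(eigval, reverse=True))
    else:
        angle, semi_axes = float("nan"), (float("nan"), float("nan"))

    return {
        "paired": paired,
        "n_paired": n,
        "n_nonprogressor_a": int((~prog_a).sum()),
        "n_nonprogressor_b": int((~prog_b).sum()),
        "median_ttp_a": float(paired["ttp_a"].median()) if n else float("nan"),
        "median_ttp_b": float(paired["ttp_b"].median()) if n else float("nan"),
        "median_benefit": float(paired["benefit"].median()) if n else float("nan"),
        "pearson": pearson,
        "ellipse_semi_axes": semi_axes,
        "ellipse_angle_rad": angle,
    }
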