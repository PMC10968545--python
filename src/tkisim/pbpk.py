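"""Whole-body perfusion-limited PBPK for an oral small molecule with an optional metabolite.

Structure
---------
Fifteen compartments: gut lumen (absorption site), eleven perfused tissues
(gut, liver, spleen, kidney, brain, heart, muscle, adipose, skin, bone,
rest-of-body), lung, arterial and venous blood.  Each perfused tissue obeys

    dA_t/dt = Q_t * (C_art - C_t * BP / Kp_t)

with amounts in mg, blood flows Q in L/h and the tissue:plasma partition
coefficient Kp referencing plasma (BP is the blood:plasma ratio).  Gut and
spleen drain through the liver (portal inflow); the lung carries the full
cardiac output and closes the venous -> lung -> arterial loop.

Oral dosing places ``F * dose`` in the gut lumen (first-order transfer ka
into gut tissue) and routes ``(1 - F) * dose`` to an unabsorbed bypass bin so
mass balance closes exactly.  Hepatic elimination is well-stirred on the
unbound liver concentration (rate = CLint * fu * C_liver / Kp_liver); a
fraction ``fm`` of it forms the metabolite in the metabolite's liver
compartment, converted by the molar-mass ratio.  Renal elimination acts on
the unbound kidney concentration.

The mouse and human settings share every equation and differ only in the
:class:`Physiology` values, which are approximate standard reference values
(the model is meant to be re-calibrated against plasma profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from tkisim.units import mg_per_l_to_nanomolar

__all__ = [
    "Physiology",
    "DrugProperties",
    "DoseRegimen",
    "simulate_pk",
    "tumor_concentration",
    "summarize_pk",
    "steady_state_organ_concentrations",
    "human_physiology",
    "mouse_physiology",
    "default_drug",
    "ORGANS",
]

# perfused tissues (lung handled separately; gut and spleen drain via liver)
ORGANS = (
    "gut", "liver", "spleen", "kidney", "brain", "heart",
    "muscle", "adipose", "skin", "bone", "rest",
)
_PORTAL = ("gut", "spleen")


@dataclass(frozen=True)
class Physiology:
    species: str
    body_mass: float  # kg
    cardiac_output: float  # L/h
    flows: dict[str, float]  # L/h per perfused tissue (liver = hepatic artery)
    volumes: dict[str, float]  # L, incl. "lung", "arterial", "venous"
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        missing = set(ORGANS) - set(self.flows)
        if missing:
            raise ValueError(f"missing flows for {sorted(missing)}")
        missing_v = (set(ORGANS) | {"lung", "arterial", "venous"}) - set(self.volumes)
        if missing_v:
            raise ValueError(f"missing volumes for {sorted(missing_v)}")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("volumes must be > 0")
        total = sum(self.flows.values())
        if abs(total - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ValueError(
                f"tissue flows sum to {total:g} L/h, expected cardiac output "
                f"{self.cardiac_output:g} L/h (lung carries the total flow)"
            )


def human_physiology(body_mass: float = 70.0) -> Physiology:
    """Reference adult physiology, flows/volumes scaled linearly with mass."""
    s = body_mass / 70.0
    co = 390.0 * s
    flows = {
        "gut": 58.5, "liver": 25.35, "spleen": 7.8, "kidney": 66.3,
        "brain": 46.8, "heart": 15.6, "muscle": 66.3, "adipose": 19.5,
        "skin": 19.5, "bone": 19.5,
    }
    flows = {k: v * s for k, v in flows.items()}
    flows["rest"] = co - sum(flows.values())
    volumes = {
        "gut": 1.65, "liver": 1.80, "spleen": 0.19, "kidney": 0.31,
        "brain": 1.45, "heart": 0.33, "muscle": 29.0, "adipose": 13.0,
        "skin": 2.60, "bone": 7.90, "rest": 3.00, "lung": 0.50,
        "arterial": 1.80, "venous": 3.60,
    }
    volumes = {k: v * s for k, v in volumes.items()}
    return Physiology("human", body_mass, co, flows, volumes)


def mouse_physiology(body_mass: float = 0.025) -> Physiology:
    """Reference mouse physiology, same equations as the human setting."""
    s = body_mass / 0.025
    co = 0.84 * s
    frac = {
        "gut": 0.141, "liver": 0.020, "spleen": 0.011, "kidney": 0.091,
        "brain": 0.033, "heart": 0.066, "muscle": 0.159, "adipose": 0.050,
        "skin": 0.058, "bone": 0.110,
    }
    flows = {k: f * co for k, f in frac.items()}
    flows["rest"] = co - sum(flows.values())
    vfrac = {
        "gut": 0.0425, "liver": 0.055, "spleen": 0.0035, "kidney": 0.017,
        "brain": 0.017, "heart": 0.005, "muscle": 0.384, "adipose": 0.070,
        "skin": 0.164, "bone": 0.107, "rest": 0.030, "lung": 0.007,
        "arterial": 0.016, "venous": 0.033,
    }
    volumes = {k: f * body_mass for k, f in vfrac.items()}  # 1 kg ~ 1 L
    return Physiology("mouse", body_mass, co, flows, volumes)


@dataclass(frozen=True)
class DrugProperties:
    """Compound-specific PK inputs.

    ``kp`` maps each perfused tissue plus ``lung`` to its tissue:plasma
    partition coefficient; ``clint_hepatic`` is intrinsic (unbound) clearance
    in L/h; ``metabolite_fraction`` is the share of hepatic elimination that
    forms the named metabolite.  Default parameter sets shipped with the
    package are starting values intended for re-calibration against plasma
    profiles, not claimed literature values.
    """

    name: str
    molar_mass: float  # g/mol
    fraction_unbound: float
    blood_plasma_ratio: float = 1.0
    absorption_rate: float = 1.0  # 1/h
    bioavailability: float = 1.0
    kp: dict[str, float] = field(default_factory=dict)
    clint_hepatic: float = 0.0  # L/h
    renal_clearance: float = 0.0  # L/h
    metabolite_fraction: float = 0.0
    tumor_scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fraction_unbound", "bioavailability", "metabolite_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clint_hepatic < 0 or self.renal_clearance < 0:
            raise ValueError("clearances must be >= 0")
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError("partition coefficients must be > 0")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")

    def kp_for(self, organ: str) -> float:
        return self.kp.get(organ, self.kp.get("default", 1.0))


def _uniform_kp(value: float, brain: float) -> dict[str, float]:
    kp = {organ: value for organ in ORGANS}
    kp["lung"] = value
    kp["brain"] = brain
    kp["default"] = value
    return kp


_DRUG_PRESETS: dict[str, DrugProperties] = {
    # starting values chosen to land in the reported plasma-exposure range;
    # refine with the calibration module
    "gefitinib": DrugProperties(
        name="gefitinib", molar_mass=446.9, fraction_unbound=0.03,
        blood_plasma_ratio=1.0, absorption_rate=0.7, bioavailability=0.60,
        kp=_uniform_kp(20.0, 2.0), clint_hepatic=933.0, renal_clearance=0.3,
        metabolite_fraction=0.0, tumor_scaling_factor=3.0,
    ),
    "osimertinib": DrugProperties(
        name="osimertinib", molar_mass=499.6, fraction_unbound=0.055,
        blood_plasma_ratio=1.0, absorption_rate=0.5, bioavailability=0.70,
        kp=_uniform_kp(16.0, 2.0), clint_hepatic=360.0, renal_clearance=0.2,
        metabolite_fraction=0.10, tumor_scaling_factor=3.0,
    ),
    "az5104": DrugProperties(
        name="az5104", molar_mass=485.6, fraction_unbound=0.05,
        blood_plasma_ratio=1.0, absorption_rate=0.5, bioavailability=0.0,
        kp=_uniform_kp(16.0, 2.0), clint_hepatic=400.0, renal_clearance=0.2,
        metabolite_fraction=0.0, tumor_scaling_factor=3.0,
    ),
}


def default_drug(name: str) -> DrugProperties:
    """Shipped starting parameter set for gefitinib, osimertinib or AZ5104."""
    try:
        return _DRUG_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"no preset drug named {name!r}")


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing. ``amount`` in mg, or mg/kg if ``per_kg``."""

    amount: float
    interval: float = 24.0  # h
    start: float = 0.0  # h
    n_doses: int = 1
    per_kg: bool = False

    def __post_init__(self) -> None:
        if self.amount < 0 or self.interval <= 0 or self.n_doses < 1:
            raise ValueError("amount >= 0, interval > 0, n_doses >= 1 required")

    def dose_mg(self, physiology: Physiology) -> float:
        return self.amount * physiology.body_mass if self.per_kg else self.amount

    def dose_times(self) -> np.ndarray:
        return self.start + self.interval * np.arange(self.n_doses)


# state layout per analyte:
#   [lumen, organs..., lung, arterial, venous, eliminated, metabolized, unabsorbed]
_N_TISSUE = len(ORGANS)
_IDX_LUMEN = 0
_IDX_LUNG = 1 + _N_TISSUE
_IDX_ART = _IDX_LUNG + 1
_IDX_VEN = _IDX_ART + 1
_IDX_ELIM = _IDX_VEN + 1
_IDX_MET = _IDX_ELIM + 1
_IDX_UNABS = _IDX_MET + 1
_BLOCK = _IDX_UNABS + 1


def _analyte_rhs(a, drug, phys, out, met_input_sink=None, met_ratio=1.0):
    """Fill ``out`` with the time derivative of one analyte block.

    Returns the hepatic metabolization rate (mg/h of parent) for coupling.
    """
    bp = drug.blood_plasma_ratio
    q_liver_total = (
        phys.flows["liver"] + phys.flows["gut"] + phys.flows["spleen"]
    )
    c_art = a[_IDX_ART] / phys.volumes["arterial"]
    c_ven = a[_IDX_VEN] / phys.volumes["venous"]

    # absorption
    absorption = drug.absorption_rate * a[_IDX_LUMEN]
    out[_IDX_LUMEN] = -absorption

    c_out = {}
    for i, organ in enumerate(ORGANS):
        c_t = a[1 + i] / phys.volumes[organ]
        c_out[organ] = c_t * bp / drug.kp_for(organ)

    venous_in = 0.0
    for i, organ in enumerate(ORGANS):
        if organ == "liver":
            inflow = (
                phys.flows["liver"] * c_art
                + phys.flows["gut"] * c_out["gut"]
                + phys.flows["spleen"] * c_out["spleen"]
            )
            out[1 + i] = inflow - q_liver_total * c_out["liver"]
            venous_in += q_liver_total * c_out["liver"]
        else:
            out[1 + i] = phys.flows[organ] * (c_art - c_out[organ])
            if organ not in _PORTAL:
                venous_in += phys.flows[organ] * c_out[organ]

    # absorption feeds gut tissue
    out[1 + ORGANS.index("gut")] += absorption

    # hepatic elimination: well-stirred on unbound liver concentration
    c_liver_plasma_unbound = (
        drug.fraction_unbound * a[1 + ORGANS.index("liver")]
        / phys.volumes["liver"] / drug.kp_for("liver")
    )
    hepatic = drug.clint_hepatic * c_liver_plasma_unbound
    out[1 + ORGANS.index("liver")] -= hepatic

    # renal elimination: unbound kidney concentration
    c_kid_plasma_unbound = (
        drug.fraction_unbound * a[1 + ORGANS.index("kidney")]
        / phys.volumes["kidney"] / drug.kp_for("kidney")
    )
    renal = drug.renal_clearance * c_kid_plasma_unbound
    out[1 + ORGANS.index("kidney")] -= renal

    # lung and blood
    c_lung_out = a[_IDX_LUNG] / phys.volumes["lung"] * bp / drug.kp_for("lung")
    out[_IDX_LUNG] = phys.cardiac_output * (c_ven - c_lung_out)
    out[_IDX_ART] = phys.cardiac_output * c_lung_out - sum(
        phys.flows[o] for o in ORGANS
    ) * c_art
    out[_IDX_VEN] = venous_in - phys.cardiac_output * c_ven

    metabolized = hepatic * drug.metabolite_fraction
    out[_IDX_ELIM] = hepatic - metabolized + renal
    out[_IDX_MET] = metabolized
    out[_IDX_UNABS] = 0.0
    return metabolized


def simulate_pk(
    drug: DrugProperties,
    physiology: Physiology,
    regimen: DoseRegimen,
    horizon: float,
    metabolite: DrugProperties | None = None,
    output_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate plasma and organ concentrations after oral dosing.

    Returns a tidy frame with columns ``time`` (h), ``species``, ``analyte``,
    ``compartment`` (``plasma``, each organ, ``lung``), ``concentration``
    (mg/L) and ``unit``.
    """
    if metabolite is None and drug.metabolite_fraction > 0:
        raise ValueError("metabolite_fraction > 0 but no metabolite supplied")
    has_met = metabolite is not None
    n = _BLOCK * (2 if has_met else 1)

    mw_ratio = (metabolite.molar_mass / drug.molar_mass) if has_met else 1.0

    def rhs(t, y):
        out = np.zeros(n)
        met_rate = _analyte_rhs(y[:_BLOCK], drug, physiology, out[:_BLOCK])
        if has_met:
            _analyte_rhs(y[_BLOCK:], metabolite, physiology, out[_BLOCK:])
            out[_BLOCK + 1 + ORGANS.index("liver")] += met_rate * mw_ratio
        return out

    dose = regimen.dose_mg(physiology)
    dose_times = [t for t in regimen.dose_times() if t <= horizon]
    if not dose_times:
        raise ValueError("horizon does not cover any dose")

    grid = np.arange(0.0, horizon + 0.5 * output_step, output_step)
    grid = grid[grid <= horizon]
    y = np.zeros(n)
    rows_t, rows_y = [], []
    breakpoints = list(dose_times) + [horizon]
    t_now = 0.0
    if grid[0] == 0.0 and dose_times and dose_times[0] > 0.0:
        rows_t.append(0.0)
        rows_y.append(y.copy())
    for i, t_next in enumerate(breakpoints):
        if t_next > t_now:
            if i < len(dose_times):
                # the state at a dose time is recorded post-dose only
                seg = grid[(grid > t_now) & (grid < t_next)]
            else:
                seg = grid[(grid > t_now) & (grid <= t_next)]
            t_eval = np.unique(np.concatenate([seg, [t_next]]))
            sol = solve_ivp(
                rhs, (t_now, t_next), y, method="LSODA",
                t_eval=t_eval, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"PK integration failed: {sol.message}")
            keep = np.isin(sol.t, seg)
            rows_t.extend(sol.t[keep])
            rows_y.extend(sol.y[:, keep].T)
            y = sol.y[:, -1].copy()
            t_now = t_next
        if i < len(dose_times):
            y[_IDX_LUMEN] += drug.bioavailability * dose
            y[_IDX_UNABS] += (1.0 - drug.bioavailability) * dose
            if t_next in grid:
                rows_t.append(t_next)
                rows_y.append(y.copy())

    times = np.asarray(rows_t)
    states = np.asarray(rows_y)

    records = []
    analytes = [(drug, 0)] + ([(metabolite, _BLOCK)] if has_met else [])
    for compound, off in analytes:
        bp = compound.blood_plasma_ratio
        plasma = states[:, off + _IDX_VEN] / physiology.volumes["venous"] / bp
        records.append(
            pd.DataFrame({
                "time": times, "species": physiology.species,
                "analyte": compound.name, "compartment": "plasma",
                "concentration": plasma, "unit": "mg/L",
            })
        )
        for organ in (*ORGANS, "lung"):
            idx = (off + _IDX_LUNG) if organ == "lung" else (off + 1 + ORGANS.index(organ))
            conc = states[:, idx] / physiology.volumes[organ]
            records.append(
                pd.DataFrame({
                    "time": times, "species": physiology.species,
                    "analyte": compound.name, "compartment": organ,
                    "concentration": conc, "unit": "mg/L",
                })
            )
    table = pd.concat(records, ignore_index=True)
    table.attrs["mass_balance"] = _mass_balance(
        times, states, dose, np.asarray(dose_times), has_met, mw_ratio
    )
    table.attrs["states"] = states
    table.attrs["times"] = times
    return table


def _mass_balance(
    times: np.ndarray,
    states: np.ndarray,
    dose: float,
    dose_times: np.ndarray,
    has_met: bool,
    mw_ratio: float,
) -> np.ndarray:
    """Relative mass-balance error at every output point.

    Cumulative administered dose must equal body burden + gut-lumen residual
    + unabsorbed bypass + eliminated + metabolized at every time; when a
    metabolite is present, parent-equivalent metabolite mass (burden plus
    eliminated, divided by the molar-mass ratio) must additionally equal the
    parent's cumulative metabolized amount.
    """
    parent = states[:, :_BLOCK]
    accounted = (
        parent[:, : _IDX_ELIM].sum(axis=1)  # lumen + tissues + blood
        + parent[:, _IDX_ELIM]
        + parent[:, _IDX_MET]
        + parent[:, _IDX_UNABS]
    )
    doses_so_far = np.array(
        [np.count_nonzero(dose_times <= t) for t in times], dtype=float
    )
    administered = dose * doses_so_far
    scale = np.maximum(administered, 1e-12)
    err = np.abs(accounted - administered) / scale
    if has_met:
        met = states[:, _BLOCK:]
        met_equiv = (met[:, : _IDX_ELIM].sum(axis=1) + met[:, _IDX_ELIM]) / mw_ratio
        met_scale = np.maximum(parent[:, _IDX_MET], 1e-12)
        err = np.maximum(err, np.abs(met_equiv - parent[:, _IDX_MET]) / met_scale)
    return err


def tumor_concentration(
    organ_conc_mg_l: np.ndarray | float,
    drug: DrugProperties,
) -> np.ndarray | float:
    """Effective (unbound intracellular) TKI concentration in nmol/L.

    The tumor is assumed to equilibrate with its host organ: the effective
    concentration is proportional (``tumor_scaling_factor``) to the unbound
    organ concentration, converted by molar mass.
    """
    unbound = np.asarray(organ_conc_mg_l, dtype=float) * drug.fraction_unbound
    eff = drug.tumor_scaling_factor * mg_per_l_to_nanomolar(1.0, drug.molar_mass) * unbound
    return float(eff) if np.isscalar(organ_conc_mg_l) else eff


def summarize_pk(
    table: pd.DataFrame,
    analyte: str | None = None,
    compartment: str = "plasma",
    interval: float | None = None,
) -> dict[str, float]:
    """Cmax, Tmax, trapezoidal AUC(0-t) and accumulation ratio for one series.

    The accumulation ratio compares the AUC over the last complete dosing
    ``interval`` with that over the first; it is ``nan`` unless the sampled
    span covers at least two intervals.
    """
    sub = table[table["compartment"] == compartment]
    if analyte is not None:
        sub = sub[sub["analyte"] == analyte]
    if sub.empty:
        raise ValueError("empty concentration series")
    t = sub["time"].to_numpy()
    c = sub["concentration"].to_numpy()
    order = np.argsort(t)
    t, c = t[order], c[order]
    auc = float(np.trapezoid(c, t))
    i = int(np.argmax(c))
    accumulation = float("nan")
    if interval is not None and t[-1] - t[0] >= 2 * interval:
        first = (t >= t[0]) & (t <= t[0] + interval)
        last = (t >= t[-1] - interval) & (t <= t[-1])
        auc_first = float(np.trapezoid(c[first], t[first]))
        auc_last = float(np.trapezoid(c[last], t[last]))
        if auc_first > 0:
            accumulation = auc_last / auc_first
    return {
        "cmax": float(c[i]),
        "tmax": float(t[i]),
        "auc": auc,
        "accumulation_ratio": accumulation,
    }


def steady_state_organ_concentrations(
    drug: DrugProperties,
    physiology: Physiology,
    regimen: DoseRegimen,
    metabolite: DrugProperties | None = None,
    n_settle_doses: int = 20,
) -> dict[str, dict[str, float]]:
    """Average organ concentrations (mg/L) over the last dosing interval.

    Runs the PBPK model to (approximate) periodic steady state under the
    regimen repeated ``n_settle_doses`` times and averages each organ's
    concentration over the final interval.  Used by the trial engine, which
    exploits the separation between the daily PK timescale and the monthly
    tumor timescale.
    """
    reg = DoseRegimen(
        amount=regimen.amount, interval=regimen.interval, start=0.0,
        n_doses=n_settle_doses, per_kg=regimen.per_kg,
    )
    horizon = reg.interval * n_settle_doses
    table = simulate_pk(
        drug, physiology, reg, horizon, metabolite=metabolite,
        output_step=reg.interval / 50.0,
    )
    t_lo = horizon - reg.interval
    out: dict[str, dict[str, float]] = {}
    for analyte_name, grp in table.groupby("analyte"):
        per_organ = {}
        for organ, sub in grp.groupby("compartment"):
            sub = sub[sub["time"] >= t_lo]
            per_organ[str(organ)] = float(
                np.trapezoid(sub["concentration"], sub["time"]) / reg.interval
            )
        out[str(analyte_name)] = per_organ
    return out
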