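"""EGFR/MET/VEGFR -> RAS/PI3K activation model with competitive ATP-site inhibition.

The growth-factor signal is reduced to two downstream hubs, RAS and PI3K.
Each hub cycles between an inactive and an active form; activation is
second-order in the inactive pool and the active-receptor concentration,
deactivation is first-order:

    dRas*/dt  = (RasT - Ras*) * (ka_met*MET* + ka_vegfr*VEGFR* + ka_egfr*EGFR**pf)
                - kda_ras * Ras*
    dPI3K*/dt = (PI3KT - PI3K*) * (... + ka_ras*Ras*) - kda_pi3k * PI3K*

where ``pf`` is the fraction of active EGFR that is phosphorylated.  A TKI
competes with ATP at the intracellular kinase domain, so

    pf = [ATP] / ([ATP] + Km_ATP * (1 + [TKI]/Ki))

with ``Km_ATP`` the ATP half-saturation constant of the (mutant) kinase and
``Ki`` the mutation- and drug-specific inhibition constant.  An alternative
reading of the published inhibition expression with a doubled constant term
(``2 + [TKI]/Ki``) is selectable via ``formula_variant="as_printed"``.

Units: concentrations in mol/L internally; the inhibition-constant table is
stored in nmol/L (the unit it is reported in) and converted at lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "SignalingParams",
    "ReceptorInputs",
    "InhibitionParams",
    "SignalingState",
    "KI_TABLE_NM",
    "ATP_AFFINITY_NM",
    "ki_lookup",
    "atp_affinity_from_row",
    "phospho_fraction",
    "ode_rhs",
    "steady_state",
    "normalized_signal",
]


@dataclass(frozen=True)
class SignalingParams:
    """Rate constants and pool sizes of the RAS/PI3K activation cycle.

    Second-order activation rates in L/mol/s, first-order deactivation rates
    in 1/s, total pools in mol/L.  Defaults for the rate constants are the
    published MAPK-cascade-derived values; the total pool sizes are not
    published and are model configuration.
    """

    ka_ras_by_met: float = 1.89e6
    ka_ras_by_vegfr: float = 1.34e3
    ka_ras_by_egfr: float = 1.89e6
    kda_ras: float = 1.0
    ka_pi3k_by_met: float = 4.69e6
    ka_pi3k_by_vegfr: float = 9.99e7
    ka_pi3k_by_egfr: float = 6.04e5
    ka_pi3k_by_ras: float = 3.94e4
    kda_pi3k: float = 1.0
    ras_total: float = 1.0e-5
    pi3k_total: float = 1.0e-5

    def __post_init__(self) -> None:
        for name in (
            "ka_ras_by_met", "ka_ras_by_vegfr", "ka_ras_by_egfr", "kda_ras",
            "ka_pi3k_by_met", "ka_pi3k_by_vegfr", "ka_pi3k_by_egfr",
            "ka_pi3k_by_ras", "kda_pi3k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ras_total <= 0 or self.pi3k_total <= 0:
            raise ValueError("total pool sizes must be > 0")


@dataclass(frozen=True)
class ReceptorInputs:
    """Active-receptor and ATP concentrations (mol/L), quasi-static."""

    egfr_active: float
    cmet_active: float = 0.0
    vegfr_active: float = 0.0
    atp: float = 1.0e-3

    def __post_init__(self) -> None:
        for name in ("egfr_active", "cmet_active", "vegfr_active", "atp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


FormulaVariant = Literal["standard", "as_printed"]


@dataclass(frozen=True)
class InhibitionParams:
    """Competitive-inhibition inputs for the phospho-fraction.

    ``ki_tki`` and ``atp_affinity`` in nmol/L, ``tki`` (effective unbound
    intracellular concentration) in nmol/L; ``atp`` must be supplied in the
    same unit when calling :func:`phospho_fraction` (the helper converts the
    mol/L internal ATP before building this object).
    """

    ki_tki: float
    atp_affinity: float
    tki: float
    formula_variant: FormulaVariant = "standard"

    def __post_init__(self) -> None:
        if self.ki_tki <= 0:
            raise ValueError("ki_tki must be > 0")
        if self.atp_affinity <= 0:
            raise ValueError("atp_affinity must be > 0")
        if self.tki < 0:
            raise ValueError("tki must be >= 0")


@dataclass
class SignalingState:
    """Active RAS and PI3K concentrations (mol/L) at a time point (s)."""

    ras_active: float
    pi3k_active: float
    time: float = 0.0


# ---------------------------------------------------------------------------
# Inhibition-constant table: (drug, mutation) -> Ki in nmol/L.
#
# Mutation keys carry the T790M gatekeeper flag where the source distinguishes
# it.  AZ5104, osimertinib's active metabolite, shares osimertinib's values.
# ---------------------------------------------------------------------------

KI_TABLE_NM: dict[tuple[str, str], float] = {
    ("gefitinib", "ex19del+t790m"): 4.3e1,
    ("osimertinib", "ex19del+t790m"): 3.2e-2,
    ("gefitinib", "ex21ins+t790m"): 2.9e1,
    ("osimertinib", "ex21ins+t790m"): 9.4e-3,
    ("gefitinib", "ex19del"): 8.3e1,
    ("osimertinib", "ex19del"): 1.1,
    ("gefitinib", "ex20_sensitive"): 2.5,
    ("osimertinib", "ex20_sensitive"): 5.9e-1,
    ("gefitinib", "ex20_resistant"): 2.6e1,
    ("osimertinib", "ex20_resistant"): 6.2,
    ("gefitinib", "ex21ins"): 6.4,
    ("osimertinib", "ex21ins"): 9.7e-1,
    ("gefitinib", "wild_type"): 1.6e1,
    ("osimertinib", "wild_type"): 3.3,
}

# Published Ki/Km_ATP ratios (dimensionless, reported as value x 1e-3).
KI_OVER_ATP_AFFINITY: dict[tuple[str, str], float] = {
    ("gefitinib", "ex19del+t790m"): 5.1e-3,
    ("osimertinib", "ex19del+t790m"): 3.8e-6,
    ("gefitinib", "ex21ins+t790m"): 3.4e-3,
    ("osimertinib", "ex21ins+t790m"): 1.1e-6,
    ("gefitinib", "ex19del"): 6.5e-6,
    ("osimertinib", "ex19del"): 8.5e-6,
    ("gefitinib", "ex20_sensitive"): 1.3e-4,
    ("osimertinib", "ex20_sensitive"): 3.1e-5,
    ("gefitinib", "ex20_resistant"): 7.0e-4,
    ("osimertinib", "ex20_resistant"): 1.7e-4,
    ("gefitinib", "ex21ins"): 4.3e-5,
    ("osimertinib", "ex21ins"): 6.5e-6,
    ("gefitinib", "wild_type"): 3.2e-3,
    ("osimertinib", "wild_type"): 6.4e-4,
}


def atp_affinity_from_row(ki_nm: float, ki_over_km: float) -> float:
    """Back-derive the ATP half-saturation constant (nmol/L) from a table row."""
    if ki_nm <= 0 or ki_over_km <= 0:
        raise ValueError("Ki and Ki/Km ratio must be > 0")
    return ki_nm / ki_over_km


# Per-mutation Km_ATP (nmol/L), back-derived from the osimertinib rows, whose
# implied values are mutually consistent across drugs for every mutation
# except exon-19-del, where the gefitinib row implies ~1.3e7 nmol/L (kept in
# KI_OVER_ATP_AFFINITY, flagged in docs, not used here: Km_ATP is a property
# of the kinase, not of the drug).
ATP_AFFINITY_NM: dict[str, float] = {
    mut: atp_affinity_from_row(
        KI_TABLE_NM[("osimertinib", mut)], KI_OVER_ATP_AFFINITY[("osimertinib", mut)]
    )
    for mut in (
        "ex19del+t790m", "ex21ins+t790m", "ex19del", "ex20_sensitive",
        "ex20_resistant", "ex21ins", "wild_type",
    )
}


def ki_lookup(drug: str, mutation: str, t790m: bool = False) -> float:
    """Ki (nmol/L) for a drug against an EGFR mutation.

    ``mutation`` is one of ``ex19del``, ``ex21ins``, ``ex20_sensitive``,
    ``ex20_resistant``, ``wild_type``; ``t790m`` selects the gatekeeper row
    where one exists.  AZ5104 maps onto osimertinib's values.
    """
    drug = drug.lower()
    if drug == "az5104":
        drug = "osimertinib"
    key_mut = mutation
    if t790m:
        if mutation not in ("ex19del", "ex21ins"):
            raise KeyError(
                f"no T790M-bearing inhibition row for mutation {mutation!r}"
            )
        key_mut = mutation + "+t790m"
    try:
        return KI_TABLE_NM[(drug, key_mut)]
    except KeyError:
        raise KeyError(f"no inhibition constant for drug={drug!r}, mutation={key_mut!r}")


def atp_affinity_lookup(mutation: str, t790m: bool = False) -> float:
    """Km_ATP (nmol/L) of the mutant kinase."""
    key_mut = mutation + "+t790m" if t790m else mutation
    try:
        return ATP_AFFINITY_NM[key_mut]
    except KeyError:
        raise KeyError(f"no ATP affinity for mutation {key_mut!r}")


def phospho_fraction(inh: InhibitionParams, atp: float) -> float:
    """Fraction of active EGFR that is phosphorylated under competitive inhibition.

    Parameters
    ----------
    inh
        Inhibition constants and TKI concentration; ``atp`` must share their
        concentration unit.
    atp
        ATP concentration, same unit as ``inh.atp_affinity``.
    """
    if atp < 0:
        raise ValueError("atp must be >= 0")
    const = 1.0 if inh.formula_variant == "standard" else 2.0
    return atp / (atp + inh.atp_affinity * (const + inh.tki / inh.ki_tki))


def ode_rhs(
    state: SignalingState,
    params: SignalingParams,
    rec: ReceptorInputs,
    pf: float,
) -> tuple[float, float]:
    """Time derivatives (mol/L/s) of active RAS and active PI3K."""
    ras_inactive = params.ras_total - state.ras_active
    pi3k_inactive = params.pi3k_total - state.pi3k_active
    a_ras = (
        params.ka_ras_by_met * rec.cmet_active
        + params.ka_ras_by_vegfr * rec.vegfr_active
        + params.ka_ras_by_egfr * rec.egfr_active * pf
    )
    d_ras = ras_inactive * a_ras - state.ras_active * params.kda_ras
    a_pi3k = (
        params.ka_pi3k_by_met * rec.cmet_active
        + params.ka_pi3k_by_vegfr * rec.vegfr_active
        + params.ka_pi3k_by_egfr * rec.egfr_active * pf
        + params.ka_pi3k_by_ras * state.ras_active
    )
    d_pi3k = pi3k_inactive * a_pi3k - state.pi3k_active * params.kda_pi3k
    return d_ras, d_pi3k


def steady_state(
    params: SignalingParams, rec: ReceptorInputs, pf: float
) -> SignalingState:
    """Unique fixed point of the two-state activation cycles.

    For constant receptor inputs the RAS equation is autonomous and linear,
    Ras* = RasT * A / (A + kda); the PI3K drive then includes the settled
    RAS term, giving the same closed form.
    """
    a_ras = (
        params.ka_ras_by_met * rec.cmet_active
        + params.ka_ras_by_vegfr * rec.vegfr_active
        + params.ka_ras_by_egfr * rec.egfr_active * pf
    )
    ras = params.ras_total * a_ras / (a_ras + params.kda_ras) if a_ras > 0 else 0.0
    a_pi3k = (
        params.ka_pi3k_by_met * rec.cmet_active
        + params.ka_pi3k_by_vegfr * rec.vegfr_active
        + params.ka_pi3k_by_egfr * rec.egfr_active * pf
        + params.ka_pi3k_by_ras * ras
    )
    pi3k = (
        params.pi3k_total * a_pi3k / (a_pi3k + params.kda_pi3k) if a_pi3k > 0 else 0.0
    )
    return SignalingState(ras_active=ras, pi3k_active=pi3k)


def normalized_signal(
    state: SignalingState,
    reference: SignalingState,
    pi3k_weight: float = 0.5,
) -> float:
    """Scalar pathway output in [0, 1] relative to the untreated reference.

    A convex combination of the PI3K and RAS activities, each normalized by
    its untreated steady-state value; drives proliferation/survival in the
    tumor layer.  Equals 1 in the absence of drug by construction.
    """
    if not 0.0 <= pi3k_weight <= 1.0:
        raise ValueError("pi3k_weight must be in [0, 1]")
    if reference.ras_active <= 0 or reference.pi3k_active <= 0:
        raise ValueError("untreated reference activities must be positive")
    value = pi3k_weight * (state.pi3k_active / reference.pi3k_active) + (
        1.0 - pi3k_weight
    ) * (state.ras_active / reference.ras_active)
    return min(1.0, max(0.0, value))
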