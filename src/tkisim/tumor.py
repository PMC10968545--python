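"""Multi-lesion, multi-subclone tumor dynamics driven by the pathway signal.

Each lesion is a set of subclones, each carrying its own mutation/resistance
profile.  A subclone's growth drive is the normalized RAS/PI3K pathway
output ``S`` in [0, 1] evaluated at the lesion-local effective TKI
concentration (quasi-steady signaling):

    dV/dt = lambda * S * V * (1 - V_tot / K)   (signal-driven proliferation)
            - delta * (1 - S) * V              (signal-deprivation death)
            - kappa_eff * V                    (immune clearance)

with ``kappa_eff = kappa * metastasis_attenuation`` for metastases.  This
logistic-with-deprivation law replaces the original growth model (whose
equations are not published) and reproduces the qualitative behaviors the
integrated model needs: decline of sensitive subclones under effective
exposure, regrowth from a resistant subclone, and weaker immune control in
metastases.

Resistance mechanisms act on the signaling inputs:

* T790M selects the gatekeeper-mutant inhibition row (high Ki for the
  reversible first-generation drug);
* C797S multiplies the irreversible drug's Ki (covalent anchoring lost);
* MET amplification scales the active-MET bypass input;
* EGFR amplification scales the active-EGFR input;
* KRAS / PIK3CA alterations impose constitutive pathway floors on ``S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from tkisim import signaling as sig

__all__ = [
    "MutationProfile",
    "Subclone",
    "Lesion",
    "GrowthParams",
    "PathwayContext",
    "subclone_signal",
    "step_lesion",
    "simulate_lesion",
    "lesion_diameter",
    "diameter_to_volume",
    "IRREVERSIBLE_DRUGS",
    "LESION_SITES",
    "EXTINCTION_VOLUME_MM3",
]

EGFR_MUTATIONS = ("ex19del", "ex21ins", "ex20_sensitive", "ex20_resistant", "wild_type")
LESION_SITES = ("lung_primary", "lung_contralateral", "liver", "brain", "bone", "adrenal")
# site -> PBPK organ supplying the lesion's drug exposure
SITE_ORGAN = {
    "lung_primary": "lung",
    "lung_contralateral": "lung",
    "liver": "liver",
    "brain": "brain",
    "bone": "bone",
    "adrenal": "rest",
}
IRREVERSIBLE_DRUGS = frozenset({"osimertinib", "az5104"})
EXTINCTION_VOLUME_MM3 = 1e-6
CELLS_PER_MM3 = 1e6  # 1e9 cells/cm^3


@dataclass(frozen=True)
class MutationProfile:
    """EGFR driver mutation plus resistance-mechanism flags."""

    egfr_mutation: str = "ex19del"
    t790m: bool = False
    c797s: bool = False
    egfr_amplification: bool = False
    met_amplification: bool = False
    kras_alteration: bool = False
    pik3ca_alteration: bool = False

    def __post_init__(self) -> None:
        if self.egfr_mutation not in EGFR_MUTATIONS:
            raise ValueError(f"unknown EGFR mutation {self.egfr_mutation!r}")

    def any_resistance(self) -> bool:
        return any(
            (self.t790m, self.c797s, self.egfr_amplification,
             self.met_amplification, self.kras_alteration, self.pik3ca_alteration)
        )


@dataclass
class Subclone:
    """One tumor-cell subpopulation: volume (mm^3) and mutation profile."""

    volume: float
    profile: MutationProfile
    is_resistant_subclone: bool = False

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0")


@dataclass
class Lesion:
    """A tumor site holding one or more subclones."""

    site: str
    subclones: list[Subclone]
    is_primary: bool = False
    appearance_time: float | None = None  # months; None = present at baseline

    def __post_init__(self) -> None:
        if self.site not in LESION_SITES:
            raise ValueError(f"unknown lesion site {self.site!r}")

    @property
    def organ(self) -> str:
        return SITE_ORGAN[self.site]

    def total_volume(self) -> float:
        return sum(sc.volume for sc in self.subclones)

    def diameter(self) -> float:
        return lesion_diameter(self)

    def detectable(self, threshold_mm: float = 10.0) -> bool:
        return self.diameter() >= threshold_mm


@dataclass(frozen=True)
class PathwayContext:
    """Baseline receptor activities feeding the signaling layer (mol/L).

    The active-receptor baselines are not published; they are model
    configuration shared by every subclone and scaled by the amplification
    resistance mechanisms.
    """

    egfr_active: float = 2.0e-7
    cmet_active: float = 1.0e-9
    vegfr_active: float = 1.0e-9
    atp: float = 1.0e-3
    params: sig.SignalingParams = field(default_factory=sig.SignalingParams)


@dataclass(frozen=True)
class GrowthParams:
    """Growth-law constants (rates per month, volumes mm^3) and resistance effects."""

    proliferation_rate: float = 1.2  # lambda, 1/month
    carrying_capacity: float = 5.0e5  # K, mm^3 (~100 mm sphere)
    deprivation_death_rate: float = 2.1  # delta, 1/month
    immune_clearance: float = 0.02  # kappa, 1/month (primary)
    metastasis_immune_attenuation: float = 0.5  # fraction of kappa in metastases
    pi3k_weight: float = 0.5  # w in the scalar pathway output
    met_amp_factor: float = 200.0
    egfr_amp_factor: float = 3.0
    c797s_ki_multiplier: float = 200.0
    kras_floor: float = 0.85
    pik3ca_floor: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.metastasis_immune_attenuation <= 1.0:
            raise ValueError("metastasis_immune_attenuation must be in [0, 1]")
        for name in (
            "proliferation_rate", "carrying_capacity", "deprivation_death_rate",
            "immune_clearance", "met_amp_factor", "egfr_amp_factor",
            "c797s_ki_multiplier", "kras_floor", "pik3ca_floor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _effective_ki_nm(profile: MutationProfile, drug: str, growth: GrowthParams) -> float:
    drug = drug.lower()
    mutation = profile.egfr_mutation
    t790m = profile.t790m and mutation in ("ex19del", "ex21ins")
    ki = sig.ki_lookup(drug, mutation, t790m=t790m)
    if profile.c797s and drug in IRREVERSIBLE_DRUGS:
        ki *= growth.c797s_ki_multiplier
    return ki


def _receptors_for(profile: MutationProfile, ctx: PathwayContext,
                   growth: GrowthParams) -> sig.ReceptorInputs:
    egfr = ctx.egfr_active * (growth.egfr_amp_factor if profile.egfr_amplification else 1.0)
    cmet = ctx.cmet_active * (growth.met_amp_factor if profile.met_amplification else 1.0)
    return sig.ReceptorInputs(
        egfr_active=egfr, cmet_active=cmet,
        vegfr_active=ctx.vegfr_active, atp=ctx.atp,
    )


def subclone_signal(
    subclone: Subclone,
    tki_conc_nm: float,
    drug: str,
    ctx: PathwayContext,
    growth: GrowthParams,
    formula_variant: str = "standard",
) -> float:
    """Normalized pathway output of one subclone under a TKI exposure.

    ``tki_conc_nm`` is the effective unbound intracellular concentration in
    nmol/L at the subclone's lesion.  Returns 1 for zero exposure and the
    constitutive floor for KRAS/PIK3CA-altered subclones at saturating
    exposure.
    """
    if tki_conc_nm < 0:
        raise ValueError("tki_conc_nm must be >= 0")
    profile = subclone.profile
    mutation = profile.egfr_mutation
    t790m = profile.t790m and mutation in ("ex19del", "ex21ins")
    km_atp_nm = sig.atp_affinity_lookup(mutation, t790m=t790m)
    ki_nm = _effective_ki_nm(profile, drug, growth)
    atp_nm = ctx.atp * 1e9  # mol/L -> nmol/L, shared unit for the ratio

    rec = _receptors_for(profile, ctx, growth)

    pf_untreated = sig.phospho_fraction(
        sig.InhibitionParams(ki_tki=ki_nm, atp_affinity=km_atp_nm, tki=0.0,
                             formula_variant=formula_variant),
        atp=atp_nm,
    )
    pf = sig.phospho_fraction(
        sig.InhibitionParams(ki_tki=ki_nm, atp_affinity=km_atp_nm, tki=tki_conc_nm,
                             formula_variant=formula_variant),
        atp=atp_nm,
    )
    reference = sig.steady_state(ctx.params, rec, pf_untreated)
    state = sig.steady_state(ctx.params, rec, pf)
    s = sig.normalized_signal(state, reference, pi3k_weight=growth.pi3k_weight)
    if profile.kras_alteration:
        s = max(s, growth.kras_floor)
    if profile.pik3ca_alteration:
        s = max(s, growth.pik3ca_floor)
    return s


def diameter_to_volume(diameter_mm: float) -> float:
    """Equivalent-sphere volume (mm^3) from a diameter (mm)."""
    return math.pi / 6.0 * diameter_mm**3


def lesion_diameter(lesion: Lesion) -> float:
    """Equivalent spherical diameter (mm): d = (6 V / pi)^(1/3)."""
    v = lesion.total_volume()
    return (6.0 * v / math.pi) ** (1.0 / 3.0) if v > 0 else 0.0


def _growth_rates(
    lesion: Lesion,
    growth: GrowthParams,
    signals: np.ndarray,
    volumes: np.ndarray,
) -> np.ndarray:
    v_tot = volumes.sum()
    kappa = growth.immune_clearance * (
        1.0 if lesion.is_primary else growth.metastasis_immune_attenuation
    )
    crowding = max(0.0, 1.0 - v_tot / growth.carrying_capacity)
    return (
        growth.proliferation_rate * signals * crowding
        - growth.deprivation_death_rate * (1.0 - signals)
        - kappa
    )


def step_lesion(
    lesion: Lesion,
    growth: GrowthParams,
    signals: np.ndarray,
    dt_months: float,
) -> None:
    """Advance a lesion's subclone volumes by one explicit step (in place).

    ``signals`` holds the per-subclone pathway output; constant TKI exposure
    makes it time-invariant, so callers precompute it once per subclone.
    Sub-extinction volumes clamp to zero.
    """
    if dt_months <= 0:
        raise ValueError("dt_months must be > 0")
    volumes = np.array([sc.volume for sc in lesion.subclones])
    rates = _growth_rates(lesion, growth, signals, volumes)
    # exponential (per-subclone) update: exact for constant rate, keeps V >= 0
    volumes = volumes * np.exp(rates * dt_months)
    volumes[volumes < EXTINCTION_VOLUME_MM3] = 0.0
    for sc, v in zip(lesion.subclones, volumes):
        sc.volume = float(v)


def simulate_lesion(
    lesion: Lesion,
    growth: GrowthParams,
    signals: np.ndarray,
    times_months: np.ndarray,
    dt_months: float = 0.05,
) -> np.ndarray:
    """Integrate one lesion and return its total volume at ``times_months``.

    Does not mutate ``lesion``.  Lesions with a positive ``appearance_time``
    hold their initial state until that time (seeding time of a metastasis).
    """
    times_months = np.asarray(times_months, dtype=float)
    volumes = np.array([sc.volume for sc in lesion.subclones], dtype=float)
    t0 = lesion.appearance_time or 0.0
    out = np.empty(times_months.shape)
    t = t0
    for j, t_target in enumerate(times_months):
        if t_target < t0:
            out[j] = volumes.sum()
            continue
        while t < t_target - 1e-12:
            step = min(dt_months, t_target - t)
            rates = _growth_rates(lesion, growth, signals, volumes)
            volumes = volumes * np.exp(rates * step)
            volumes[volumes < EXTINCTION_VOLUME_MM3] = 0.0
            t += step
        out[j] = volumes.sum()
    return out
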