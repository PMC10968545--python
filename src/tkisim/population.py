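"""Virtual-patient sampling: descriptors, lesions and resistance draws.

A :class:`PopulationSpec` holds the marginal distributions of the patient
descriptors (sex, age, smoking, ethnicity, stage, EGFR mutation), the
per-mechanism Bernoulli prevalences of the resistance mechanisms carried by
the resistant subclone, and the lesion-geometry configuration.  Sampling is
fully reproducible: a master seed spawns one child seed per patient.

Two concrete specs ship with the package:

* :func:`make_effect_model_spec` — the advanced EGFR-mutated LUAD
  population used for the paired (effect-model) trial, built from published
  marginal splits (sex 1:2, age 67 +/- 11, smoking 28/34/38, ethnicity
  55/45, EGFR exon 19/20/21 = 51.6/13.2/35.2%);
* :func:`make_li_cohort_spec` — the 102-patient retrospective gefitinib vs
  osimertinib cohort (arm sizes 49/53; pooled marginals of the printed
  sex, age, smoking and stage splits), with a 10x multiplier for in-silico
  replication.

Metastases copy the primary tumor's resistance profile with the concordance
probability (default 0.70) and are redrawn independently otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tkisim.tumor import (
    Lesion,
    MutationProfile,
    Subclone,
    diameter_to_volume,
)

__all__ = [
    "PopulationSpec",
    "VirtualPatient",
    "sample_population",
    "make_effect_model_spec",
    "make_li_cohort_spec",
    "population_table",
    "lesion_table",
    "DEFAULT_RESISTANCE_PREVALENCE",
    "LI_ARM_SIZES",
]

# Placeholder per-mechanism Bernoulli prevalences (the source prevalence
# literature is cited but unquantified in the model description).  Flattened
# across treatment contexts so a patient's single resistant profile is valid
# under either drug: T790M only degrades the reversible drug, C797S only the
# irreversible one, bypass mechanisms degrade both.
DEFAULT_RESISTANCE_PREVALENCE: dict[str, float] = {
    "t790m": 0.55,
    "met_amplification": 0.10,
    "c797s": 0.07,
    "egfr_amplification": 0.03,
    "kras_alteration": 0.04,
    "pik3ca_alteration": 0.07,
}

_MET_SITES = ("lung_contralateral", "liver", "bone", "brain", "adrenal")
_MET_SITE_PROBS = (0.30, 0.25, 0.25, 0.10, 0.10)


def _check_dist(name: str, dist: dict[str, float]) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total!r}, expected 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} contains negative probabilities")


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for a virtual population."""

    n_patients: int | None = None
    reference_cohort_size: int | None = None
    multiplier: int = 1
    sex_dist: dict[str, float] = field(
        default_factory=lambda: {"M": 1 / 3, "F": 2 / 3}
    )
    age_mean: float = 67.0
    age_sd: float = 11.0
    smoking_dist: dict[str, float] = field(
        default_factory=lambda: {"never": 0.28, "former": 0.34, "current": 0.38}
    )
    ethnicity_dist: dict[str, float] = field(
        default_factory=lambda: {"asian": 0.55, "other": 0.45}
    )
    stage_dist: dict[str, float] = field(
        default_factory=lambda: {"IIIb": 0.637, "IV": 0.363}
    )
    egfr_mutation_dist: dict[str, float] = field(
        default_factory=lambda: {"ex19": 0.516, "ex20": 0.132, "ex21": 0.352}
    )
    ex20_resistant_fraction: float = 0.5
    resistance_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESISTANCE_PREVALENCE)
    )
    concordance: float = 0.70
    # lesion geometry
    primary_diameter_median_mm: float = 30.0
    primary_diameter_sigma: float = 0.35
    met_diameter_median_mm: float = 15.0
    met_diameter_sigma: float = 0.40
    micromet_diameter_median_mm: float = 2.0
    micromet_diameter_sigma: float = 0.50
    n_micromets: int = 2
    mean_extra_detectable_mets: float = 1.0  # stage IV: 1 + Poisson(mean), capped
    max_detectable_mets: int = 4
    resistant_subclone_fraction: float = 1e-4
    # inter-patient variability of the proliferation rate (lognormal sigma)
    growth_rate_sigma: float = 0.40
    detect_threshold_mm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("sex_dist", "smoking_dist", "ethnicity_dist",
                     "stage_dist", "egfr_mutation_dist"):
            _check_dist(name, getattr(self, name))
        for mech, p in self.resistance_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {mech!r} must be in [0, 1]")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if not 0.0 <= self.ex20_resistant_fraction <= 1.0:
            raise ValueError("ex20_resistant_fraction must be in [0, 1]")
        if self.n_patients is None and self.reference_cohort_size is None:
            raise ValueError("either n_patients or reference_cohort_size required")
        if self.n_patients is not None and self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")

    def resolved_n(self) -> int:
        if self.n_patients is not None:
            return self.n_patients
        return self.reference_cohort_size * self.multiplier


@dataclass
class VirtualPatient:
    """One sampled patient: descriptors, lesions and resistance draws."""

    id: int
    seed: int
    sex: str
    age: float
    smoking: str
    ethnicity: str
    stage: str
    egfr_mutation: str  # inhibition-table key (ex19del, ex20_sensitive, ...)
    lesions: list[Lesion]
    primary_resistance: MutationProfile
    concordant: bool
    growth_multiplier: float = 1.0

    def detectable_metastases(self, threshold_mm: float = 10.0) -> list[Lesion]:
        return [
            les for les in self.lesions
            if not les.is_primary and les.detectable(threshold_mm)
        ]


def _draw_mutation(spec: PopulationSpec, rng: np.random.Generator) -> str:
    exon = rng.choice(
        list(spec.egfr_mutation_dist), p=list(spec.egfr_mutation_dist.values())
    )
    if exon == "ex19":
        return "ex19del"
    if exon == "ex21":
        return "ex21ins"
    if rng.random() < spec.ex20_resistant_fraction:
        return "ex20_resistant"
    return "ex20_sensitive"


def _draw_resistance(
    mutation: str, spec: PopulationSpec, rng: np.random.Generator
) -> MutationProfile:
    flags = {
        mech: bool(rng.random() < p)
        for mech, p in spec.resistance_prevalence.items()
    }
    if mutation not in ("ex19del", "ex21ins"):
        flags["t790m"] = False  # gatekeeper inhibition rows exist only for ex19/ex21
    return MutationProfile(egfr_mutation=mutation, **flags)


def _make_lesion(
    site: str,
    diameter_mm: float,
    mutation: str,
    resistance: MutationProfile,
    resistant_fraction: float,
    is_primary: bool,
) -> Lesion:
    volume = diameter_to_volume(diameter_mm)
    sensitive = Subclone(
        volume=volume * (1.0 - resistant_fraction),
        profile=MutationProfile(egfr_mutation=mutation),
    )
    resistant = Subclone(
        volume=volume * resistant_fraction,
        profile=resistance,
        is_resistant_subclone=True,
    )
    return Lesion(site=site, subclones=[sensitive, resistant], is_primary=is_primary)


def _sample_patient(
    pid: int, spec: PopulationSpec, child: np.random.SeedSequence
) -> VirtualPatient:
    rng = np.random.default_rng(child)
    seed = int(child.generate_state(1)[0] % 2**31)

    sex = rng.choice(list(spec.sex_dist), p=list(spec.sex_dist.values()))
    age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 100.0))
    smoking = rng.choice(list(spec.smoking_dist), p=list(spec.smoking_dist.values()))
    ethnicity = rng.choice(
        list(spec.ethnicity_dist), p=list(spec.ethnicity_dist.values())
    )
    stage = rng.choice(list(spec.stage_dist), p=list(spec.stage_dist.values()))
    mutation = _draw_mutation(spec, rng)

    primary_resistance = _draw_resistance(mutation, spec, rng)
    concordant = bool(rng.random() < spec.concordance)

    lesions: list[Lesion] = []
    d_primary = spec.primary_diameter_median_mm * math.exp(
        rng.normal(0.0, spec.primary_diameter_sigma)
    )
    lesions.append(
        _make_lesion(
            "lung_primary", d_primary, mutation, primary_resistance,
            spec.resistant_subclone_fraction, is_primary=True,
        )
    )

    def met_profile() -> MutationProfile:
        if concordant:
            return primary_resistance
        return _draw_resistance(mutation, spec, rng)

    if stage == "IV":
        n_det = 1 + int(rng.poisson(spec.mean_extra_detectable_mets))
        n_det = min(n_det, spec.max_detectable_mets)
        for _ in range(n_det):
            site = rng.choice(_MET_SITES, p=_MET_SITE_PROBS)
            d = 0.0
            while d < spec.detect_threshold_mm:  # detectable by construction
                d = spec.met_diameter_median_mm * math.exp(
                    rng.normal(0.0, spec.met_diameter_sigma)
                )
            lesions.append(
                _make_lesion(site, d, mutation, met_profile(),
                             spec.resistant_subclone_fraction, is_primary=False)
            )

    for _ in range(spec.n_micromets):
        site = rng.choice(_MET_SITES, p=_MET_SITE_PROBS)
        d = spec.micromet_diameter_median_mm * math.exp(
            rng.normal(0.0, spec.micromet_diameter_sigma)
        )
        d = min(d, 0.9 * spec.detect_threshold_mm)  # micromets start undetectable
        lesions.append(
            _make_lesion(site, d, mutation, met_profile(),
                         spec.resistant_subclone_fraction, is_primary=False)
        )

    growth_multiplier = float(math.exp(rng.normal(0.0, spec.growth_rate_sigma)))

    return VirtualPatient(
        id=pid, seed=seed, sex=str(sex), age=age, smoking=str(smoking),
        ethnicity=str(ethnicity), stage=str(stage), egfr_mutation=mutation,
        lesions=lesions, primary_resistance=primary_resistance,
        concordant=concordant, growth_multiplier=growth_multiplier,
    )


def sample_population(spec: PopulationSpec, master_seed: int) -> list[VirtualPatient]:
    """Sample a reproducible virtual population.

    The master seed spawns one independent child seed per patient, so
    identical master seeds give bit-identical populations and per-patient
    simulations are insensitive to execution order.
    """
    n = spec.resolved_n()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n)
    return [_sample_patient(i, spec, child) for i, child in enumerate(children)]


def make_effect_model_spec(**overrides) -> PopulationSpec:
    """Population spec for the paired effect-model trial (10 x 102 patients).

    Descriptor marginals follow the published advanced EGFR-mutated LUAD
    virtual-population table; the stage split (absent from that table)
    reuses the pooled retrospective-cohort split.
    """
    base: dict = dict(reference_cohort_size=102, multiplier=10)
    base.update(overrides)
    return PopulationSpec(**base)


LI_ARM_SIZES = {"osimertinib": 49, "gefitinib": 53}


def make_li_cohort_spec(**overrides) -> PopulationSpec:
    """Population spec mirroring the 102-patient retrospective cohort.

    Arm sizes 49 (osimertinib) and 53 (gefitinib); pooled marginals of the
    printed splits: sex M (24+26)/102, age under 65 (27+25)/102, smokers
    (38+35)/102, stage IIIb (30+35)/102.  Age maps onto a normal whose
    under-65 mass matches the printed split.
    """
    p_m = (24 + 26) / 102
    p_smoker = (38 + 35) / 102
    p_iiib = (30 + 35) / 102
    base: dict = dict(
        reference_cohort_size=102,
        multiplier=10,
        sex_dist={"M": p_m, "F": 1 - p_m},
        age_mean=65.0,  # under-65 split is (27+25)/102 ~ 0.51
        age_sd=10.0,
        smoking_dist={"never": 1 - p_smoker, "former": p_smoker / 2,
                      "current": p_smoker / 2},
        stage_dist={"IIIb": p_iiib, "IV": 1 - p_iiib},
        ethnicity_dist={"asian": 1.0, "other": 0.0},
    )
    base.update(overrides)
    return PopulationSpec(**base)


def population_table(patients: list[VirtualPatient]) -> pd.DataFrame:
    """One-row-per-patient descriptor table (CSV-friendly)."""
    rows = []
    for p in patients:
        rows.append({
            "patient": p.id,
            "seed": p.seed,
            "sex": p.sex,
            "age": p.age,
            "smoking": p.smoking,
            "ethnicity": p.ethnicity,
            "stage": p.stage,
            "egfr_mutation": p.egfr_mutation,
            "concordant": p.concordant,
            "n_lesions": len(p.lesions),
            "growth_multiplier": p.growth_multiplier,
            "t790m": p.primary_resistance.t790m,
            "met_amplification": p.primary_resistance.met_amplification,
            "egfr_amplification": p.primary_resistance.egfr_amplification,
            "kras_alteration": p.primary_resistance.kras_alteration,
            "pik3ca_alteration": p.primary_resistance.pik3ca_alteration,
            "c797s": p.primary_resistance.c797s,
        })
    return pd.DataFrame(rows)


def lesion_table(patients: list[VirtualPatient]) -> pd.DataFrame:
    """Companion lesion table: one row per lesion."""
    rows = []
    for p in patients:
        for j, les in enumerate(p.lesions):
            rows.append({
                "patient": p.id,
                "lesion": j,
                "site": les.site,
                "is_primary": les.is_primary,
                "diameter_mm": les.diameter(),
                "volume_mm3": les.total_volume(),
            })
    return pd.DataFrame(rows)
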