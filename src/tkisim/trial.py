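"""In-silico trial arm: coupled PK -> signaling -> tumor simulation with RECIST 1.1.

Per patient, the engine (i) obtains the steady-state organ exposure of the
arm's drug from the PBPK layer (daily dosing reaches periodic steady state
within days, so the average concentration over one dosing interval is reused
across the months-long tumor timescale), (ii) integrates every lesion's
subclone dynamics under its host organ's effective concentration, and (iii)
applies RECIST 1.1 at scheduled assessments:

* target lesions: up to 5 lesions detectable at baseline, at most 2 per
  site, largest first; their sum of longest (equivalent-sphere) diameters
  (SLD) is tracked against its nadir;
* progressive disease when SLD >= 1.2 x nadir AND the absolute increase is
  >= 5 mm, or when a lesion that was not detectable at baseline first
  exceeds the detectability threshold (new lesion);
* time to progression (TTP) is the first qualifying assessment time;
  patients without progression are censored at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tkisim.pbpk import (
    DoseRegimen,
    DrugProperties,
    Physiology,
    default_drug,
    human_physiology,
    steady_state_organ_concentrations,
    tumor_concentration,
)
from tkisim.population import VirtualPatient
from tkisim.tumor import (
    GrowthParams,
    Lesion,
    PathwayContext,
    simulate_lesion,
    subclone_signal,
)
from tkisim.units import weeks_to_months

__all__ = [
    "TrialDesign",
    "PatientOutcome",
    "arm_exposure",
    "simulate_patient",
    "run_arm",
    "default_regimen",
]

_DEFAULT_REGIMENS = {
    "gefitinib": DoseRegimen(amount=250.0, interval=24.0, n_doses=1),
    "osimertinib": DoseRegimen(amount=80.0, interval=24.0, n_doses=1),
}


def default_regimen(drug: str) -> DoseRegimen:
    """Standard daily oral regimen (250 mg gefitinib, 80 mg osimertinib)."""
    try:
        return _DEFAULT_REGIMENS[drug.lower()]
    except KeyError:
        raise KeyError(f"no default regimen for drug {drug!r}")


@dataclass(frozen=True)
class TrialDesign:
    """Arm drug, regimen and RECIST assessment schedule."""

    drug: str
    regimen: DoseRegimen | None = None
    horizon_months: float = 24.0
    assessment_interval_weeks: float = 6.0
    detect_threshold_mm: float = 10.0
    max_target_lesions: int = 5
    max_target_per_site: int = 2
    growth: GrowthParams = field(default_factory=GrowthParams)
    pathway: PathwayContext = field(default_factory=PathwayContext)
    ki_scale: float = 1.0  # >1 weakens the drug uniformly (sensitivity analyses)
    tumor_dt_months: float = 0.05

    def __post_init__(self) -> None:
        if self.horizon_months <= 0 or self.assessment_interval_weeks <= 0:
            raise ValueError("horizon and assessment interval must be > 0")

    def resolved_regimen(self) -> DoseRegimen:
        return self.regimen if self.regimen is not None else default_regimen(self.drug)

    def assessment_times(self) -> np.ndarray:
        """Assessment grid in months (baseline excluded), capped at horizon."""
        step = weeks_to_months(self.assessment_interval_weeks)
        times = np.arange(step, self.horizon_months + 1e-9, step)
        return times


@dataclass
class PatientOutcome:
    """TTP (months) with event flag and progression cause."""

    patient: int
    ttp: float
    event: bool
    cause: str  # "target_lesion_growth", "new_lesion" or "none"
    sld_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.event and self.cause == "none":
            raise ValueError("progressing patients need a cause")
        if not self.event and self.cause != "none":
            raise ValueError("censored patients have cause 'none'")


def arm_exposure(
    design: TrialDesign,
    physiology: Physiology | None = None,
    drug_props: DrugProperties | None = None,
    metabolite_props: DrugProperties | None = None,
) -> dict[str, float]:
    """Steady-state effective tumor concentration (nmol/L) per organ.

    For osimertinib the active metabolite AZ5104 shares the parent's
    inhibition constants, so its effective concentration simply adds to the
    parent's.
    """
    physiology = physiology or human_physiology()
    drug = drug_props or default_drug(design.drug)
    metabolite = metabolite_props
    if metabolite is None and drug.metabolite_fraction > 0:
        metabolite = default_drug("az5104")
    organ_conc = steady_state_organ_concentrations(
        drug, physiology, design.resolved_regimen(), metabolite=metabolite
    )
    exposure: dict[str, float] = {}
    for organ, conc in organ_conc[drug.name].items():
        exposure[organ] = float(tumor_concentration(conc, drug))
    if metabolite is not None:
        for organ, conc in organ_conc[metabolite.name].items():
            exposure[organ] += float(tumor_concentration(conc, metabolite))
    return exposure


def _target_lesions(
    lesions: list[Lesion], design: TrialDesign
) -> list[int]:
    """Indices of baseline target lesions: largest first, site quota applied."""
    detectable = [
        (i, les) for i, les in enumerate(lesions)
        if les.detectable(design.detect_threshold_mm)
        and (les.appearance_time is None or les.appearance_time <= 0)
    ]
    detectable.sort(key=lambda item: -item[1].diameter())
    chosen: list[int] = []
    per_site: dict[str, int] = {}
    for i, les in detectable:
        if len(chosen) >= design.max_target_lesions:
            break
        if per_site.get(les.site, 0) >= design.max_target_per_site:
            continue
        chosen.append(i)
        per_site[les.site] = per_site.get(les.site, 0) + 1
    return chosen


def evaluate_recist(
    sld: np.ndarray,
    new_lesion_at: np.ndarray,
    times: np.ndarray,
    horizon: float,
) -> tuple[float, bool, str]:
    """Apply the RECIST 1.1 progression rule to an assessed SLD series.

    ``sld[0]`` is the baseline sum of diameters (mm); ``times`` are the
    post-baseline assessment times (months) matching ``sld[1:]``;
    ``new_lesion_at`` flags, per post-baseline assessment, whether any
    non-baseline lesion is newly detectable.
    """
    nadir = sld[0]
    for k, t in enumerate(times):
        current = sld[k + 1]
        if new_lesion_at[k]:
            return float(t), True, "new_lesion"
        if current >= 1.2 * nadir and (current - nadir) >= 5.0:
            return float(t), True, "target_lesion_growth"
        nadir = min(nadir, current)
    return float(horizon), False, "none"


def simulate_patient(
    patient: VirtualPatient,
    design: TrialDesign,
    exposure: dict[str, float] | None = None,
    keep_trajectories: bool = False,
) -> PatientOutcome:
    """Simulate one patient under the arm's drug and score RECIST 1.1."""
    if exposure is None:
        exposure = arm_exposure(design)
    growth = replace(
        design.growth,
        proliferation_rate=design.growth.proliferation_rate * patient.growth_multiplier,
    )
    times = design.assessment_times()
    diam = np.empty((len(patient.lesions), len(times) + 1))
    for i, les in enumerate(patient.lesions):
        conc = exposure[les.organ] / design.ki_scale
        signals = np.array([
            subclone_signal(sc, conc, design.drug, design.pathway, growth)
            for sc in les.subclones
        ])
        vols = simulate_lesion(
            les, growth, signals, np.concatenate([[0.0], times]),
            dt_months=design.tumor_dt_months,
        )
        diam[i] = (6.0 * vols / np.pi) ** (1.0 / 3.0)

    target_idx = _target_lesions(patient.lesions, design)
    if target_idx:
        sld = diam[target_idx].sum(axis=0)
    else:
        sld = np.zeros(len(times) + 1)
    non_target = [i for i in range(len(patient.lesions)) if i not in target_idx]
    baseline_detectable = {
        i for i in non_target
        if diam[i, 0] >= design.detect_threshold_mm
    }
    new_lesion_at = np.zeros(len(times), dtype=bool)
    for i in non_target:
        if i in baseline_detectable:
            continue
        crossed = diam[i, 1:] >= design.detect_threshold_mm
        new_lesion_at |= crossed

    ttp, event, cause = evaluate_recist(sld, new_lesion_at, times, design.horizon_months)
    return PatientOutcome(
        patient=patient.id, ttp=ttp, event=event, cause=cause,
        sld_series=sld if keep_trajectories else None,
    )


def lesion_trajectories(
    patient: VirtualPatient,
    design: TrialDesign,
    exposure: dict[str, float] | None = None,
    times_months: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per-subclone volume/diameter trajectories for one patient.

    Columns: ``time``, ``patient``, ``lesion``, ``subclone``, ``volume``,
    ``diameter`` (lesion-level equivalent-sphere diameter).
    """
    if exposure is None:
        exposure = arm_exposure(design)
    if times_months is None:
        times_months = np.concatenate([[0.0], design.assessment_times()])
    growth = replace(
        design.growth,
        proliferation_rate=design.growth.proliferation_rate * patient.growth_multiplier,
    )
    rows = []
    for i, les in enumerate(patient.lesions):
        conc = exposure[les.organ] / design.ki_scale
        signals = np.array([
            subclone_signal(sc, conc, design.drug, design.pathway, growth)
            for sc in les.subclones
        ])
        joint = _subclone_trajectories(les, growth, signals, times_months,
                                       design.tumor_dt_months)
        total = joint.sum(axis=0)
        diam = (6.0 * total / np.pi) ** (1.0 / 3.0)
        for j in range(len(les.subclones)):
            for k, t in enumerate(times_months):
                rows.append({
                    "time": float(t), "patient": patient.id, "lesion": i,
                    "subclone": j, "volume": float(joint[j, k]),
                    "diameter": float(diam[k]),
                })
    return pd.DataFrame(rows)


def _subclone_trajectories(lesion, growth, signals, times_months, dt_months):
    """Per-subclone volumes at the requested times (joint integration)."""
    from tkisim.tumor import EXTINCTION_VOLUME_MM3, _growth_rates

    times_months = np.asarray(times_months, dtype=float)
    volumes = np.array([sc.volume for sc in lesion.subclones], dtype=float)
    t0 = lesion.appearance_time or 0.0
    out = np.empty((len(volumes), len(times_months)))
    t = t0
    for k, t_target in enumerate(times_months):
        if t_target >= t0:
            while t < t_target - 1e-12:
                step = min(dt_months, t_target - t)
                rates = _growth_rates(lesion, growth, signals, volumes)
                volumes = volumes * np.exp(rates * step)
                volumes[volumes < EXTINCTION_VOLUME_MM3] = 0.0
                t += step
        out[:, k] = volumes
    return out


def run_arm(
    population: list[VirtualPatient],
    design: TrialDesign,
    exposure: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate an arm and return the event table.

    Columns: ``patient``, ``arm``, ``ttp_months``, ``event``, ``cause``.
    Patients are independent (per-patient state was sealed at sampling), so
    results do not depend on iteration order; the PBPK exposure is computed
    once per arm.
    """
    if exposure is None:
        exposure = arm_exposure(design)
    rows = []
    for patient in population:
        outcome = simulate_patient(patient, design, exposure=exposure)
        rows.append({
            "patient": outcome.patient,
            "arm": design.drug,
            "ttp_months": outcome.ttp,
            "event": outcome.event,
            "cause": outcome.cause,
        })
    columns = ["patient", "arm", "ttp_months", "event", "cause"]
    return pd.DataFrame(rows, columns=columns)
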