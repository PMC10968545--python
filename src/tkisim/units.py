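"""Centralized unit conversions.

Internal conventions: signaling concentrations in mol/L, PK amounts in mg and
concentrations in mg/L, PK time in hours, trial time in months. Everything
that crosses one of these boundaries goes through this module.
"""

NM_PER_M = 1e9  # nmol/L per mol/L

HOURS_PER_DAY = 24.0
DAYS_PER_MONTH = 30.4375  # 365.25 / 12
HOURS_PER_MONTH = HOURS_PER_DAY * DAYS_PER_MONTH
DAYS_PER_WEEK = 7.0


def nanomolar_to_molar(c_nm: float) -> float:
    """nmol/L -> mol/L."""
    return c_nm / NM_PER_M


def molar_to_nanomolar(c_m: float) -> float:
    """mol/L -> nmol/L."""
    return c_m * NM_PER_M


def mg_per_l_to_nanomolar(c_mg_l: float, molar_mass_g_mol: float) -> float:
    """Mass concentration (mg/L) -> nmol/L given the molar mass (g/mol)."""
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")
    # mg/L = 1e-3 g/L; divide by g/mol -> mol/L; -> nmol/L
    return c_mg_l * 1e-3 / molar_mass_g_mol * NM_PER_M


def weeks_to_months(weeks: float) -> float:
    return weeks * DAYS_PER_WEEK / DAYS_PER_MONTH


def months_to_hours(months: float) -> float:
    return months * HOURS_PER_MONTH
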