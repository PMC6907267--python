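"""Bramwell-Hill reference PWV from lumen areas and central pulse pressure.

The Bramwell-Hill model links local pulse wave velocity to vessel
distensibility D and blood density rho:  PWV = 1 / sqrt(rho D), with
D = (A_sys - A_dia) / (A_dia * PP) the fractional systolic area change per
unit central pulse pressure.  This 4D-flow-independent estimate serves as a
comparator for the transit-time and plane-fitting strategies.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "MMHG_TO_PA",
    "BLOOD_DENSITY_KG_M3",
    "distensibility",
    "bramwell_hill_pwv",
    "bramwell_hill_from_areas",
    "process_table",
]

MMHG_TO_PA = 133.322
#: default blood density, kg/m^3
BLOOD_DENSITY_KG_M3 = 1060.0


def distensibility(
    area_sys_mm2: float, area_dia_mm2: float, pulse_pressure_mmhg: float
) -> float:
    """Aortic distensibility in 1/Pa from systolic/diastolic lumen areas.

    Areas may be in any common unit (the strain is dimensionless); pulse
    pressure is given in mmHg and converted to Pa internally.
    """
    if area_dia_mm2 <= 0:
        raise ValueError("diastolic area must be positive")
    if area_sys_mm2 < area_dia_mm2:
        raise ValueError("systolic area below diastolic area is non-physiologic")
    if pulse_pressure_mmhg <= 0:
        raise ValueError("pulse pressure must be positive")
    strain = (area_sys_mm2 - area_dia_mm2) / area_dia_mm2
    return strain / (pulse_pressure_mmhg * MMHG_TO_PA)


def bramwell_hill_pwv(
    distensibility_pa: float, rho_kg_m3: float = BLOOD_DENSITY_KG_M3
) -> float:
    """PWV (m/s) = 1 / sqrt(rho x distensibility)."""
    if distensibility_pa <= 0 or rho_kg_m3 <= 0:
        raise ValueError("distensibility and density must be positive")
    return 1.0 / math.sqrt(rho_kg_m3 * distensibility_pa)


def bramwell_hill_from_areas(
    area_sys_mm2: float,
    area_dia_mm2: float,
    pulse_pressure_mmhg: float,
    rho_kg_m3: float = BLOOD_DENSITY_KG_M3,
) -> float:
    """Convenience composition of :func:`distensibility` and :func:`bramwell_hill_pwv`."""
    return bramwell_hill_pwv(
        distensibility(area_sys_mm2, area_dia_mm2, pulse_pressure_mmhg), rho_kg_m3
    )


def process_table(df: pd.DataFrame, rho_kg_m3: float = BLOOD_DENSITY_KG_M3) -> pd.DataFrame:
    """Add distensibility and BH-PWV columns to a per-subject table.

    Expects columns ``subject_id``, ``area_sys_mm2``, ``area_dia_mm2``,
    ``pp_mmHg``.
    """
    required = {"subject_id", "area_sys_mm2", "area_dia_mm2", "pp_mmHg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["distensibility_per_pa"] = [
        distensibility(r.area_sys_mm2, r.area_dia_mm2, r.pp_mmHg)
        for r in df.itertuples()
    ]
    out["bh_pwv_m_s"] = [
        bramwell_hill_pwv(d, rho_kg_m3) for d in out["distensibility_per_pa"]
    ]
    return out
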