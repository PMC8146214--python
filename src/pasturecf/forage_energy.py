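"""Stage 1: herbage energy supply -> potential milk yield and feed intake.

The energy requirement per kg of energy-corrected milk (ECM) is a linear
function of milk fat and protein content,

    NEL (MJ/kg ECM) = 0.38 * fat% + 0.21 * protein% + 1.05,

and the potential pasture milk yield of a treatment follows from its
measured herbage NEL yield.  Because part of the herbage energy covers
maintenance, activity and losses (maintenance is assumed covered by the
concentrate supplement only in part), a single scalar `utilization` maps
gross energy yield to saleable milk; it is calibrated once on the control
treatment and applied everywhere (see :mod:`pasturecf.calibration`).

Daily dry-matter intake per cow is a linear function of live weight and
daily milk yield with config-exposed coefficients, standing in for the
standard feed-intake regressions whose coefficients are not part of the
packaged data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .scenario_model import HerdParameters, IntakeCoefficients, ModelConstants

__all__ = [
    "MilkEnergyRequirement",
    "IntakeProfile",
    "nel_per_kg_ecm",
    "potential_milk_yield",
    "estimate_dm_intake",
    "herbage_cp_content",
    "milk_per_cow_per_day",
]

DAYS_PER_YEAR = 365.0


def _check_finite_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class MilkEnergyRequirement:
    """Energy needed per kg ECM, with the composition it was computed from."""

    nel_per_kg_ecm: float
    fat_pct: float
    protein_pct: float

    def __post_init__(self) -> None:
        if self.nel_per_kg_ecm < 1.05:
            raise ValueError("nel_per_kg_ecm below the 1.05 MJ intercept bound")

    @classmethod
    def from_composition(cls, fat_pct: float, protein_pct: float) -> "MilkEnergyRequirement":
        return cls(nel_per_kg_ecm(fat_pct, protein_pct), fat_pct, protein_pct)


@dataclass(frozen=True)
class IntakeProfile:
    """Per-cow daily intake split into pasture and concentrate components."""

    dm_intake_total: float          # kg DM/cow/day
    dm_intake_pasture: float
    dm_intake_supplement: float
    cp_intake: float                # g CP/cow/day
    diet_cp_content: float          # g CP/kg DM

    def __post_init__(self) -> None:
        if abs(self.dm_intake_total
               - (self.dm_intake_pasture + self.dm_intake_supplement)) > 1e-9:
            raise ValueError("total intake must equal pasture + supplement")
        if self.dm_intake_total != 0.0 and not (5.0 <= self.dm_intake_total <= 30.0):
            raise ValueError(
                f"daily DM intake {self.dm_intake_total:.1f} kg outside the "
                "[5, 30] plausibility band"
            )


def nel_per_kg_ecm(fat_pct: float, protein_pct: float) -> float:
    """Net energy for lactation required per kg ECM, MJ.

    Linear in milk fat and protein percentage with a 1.05 MJ intercept.
    At the herd composition of 4.9% fat / 3.7% protein this is 3.689 MJ/kg.
    """
    for name, value in (("fat_pct", fat_pct), ("protein_pct", protein_pct)):
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")
        if value < 0 or value >= 100:
            raise ValueError(f"{name} must be in [0, 100), got {value}")
    return 0.38 * fat_pct + 0.21 * protein_pct + 1.05


def potential_milk_yield(
    energy_yield: float,
    req: MilkEnergyRequirement | float,
    utilization: float,
) -> float:
    """Potential milk yield from herbage energy, t ECM/ha/yr.

    Parameters
    ----------
    energy_yield : float
        Herbage energy yield, GJ NEL/ha/yr (>= 0).
    req : MilkEnergyRequirement or float
        Energy requirement per kg ECM (MJ).
    utilization : float
        Fraction of the gross energy yield realized as milk energy, in
        (0, 1].  This single scalar folds together herbage utilization and
        the non-milk (maintenance/activity) energy allocation.
    """
    if not (0.0 < utilization <= 1.0):
        raise ValueError(f"utilization must be in (0, 1], got {utilization}")
    if energy_yield < 0 or not math.isfinite(energy_yield):
        raise ValueError(f"energy_yield must be finite and >= 0, got {energy_yield}")
    nel = req.nel_per_kg_ecm if isinstance(req, MilkEnergyRequirement) else float(req)
    _check_finite_positive("nel_per_kg_ecm", nel)
    # GJ/ha * (1000 MJ/GJ) / (MJ/kg) = kg/ha; /1000 -> t/ha.  The factors cancel.
    return energy_yield * utilization / nel


def herbage_cp_content(n_yield: float, dm_yield: float) -> float:
    """Herbage crude-protein content, g CP per kg DM.

    CP = 6.25 x N; ``n_yield`` in kg N/ha, ``dm_yield`` in t DM/ha.
    """
    if dm_yield <= 0:
        raise ValueError("dm_yield must be positive")
    if n_yield < 0:
        raise ValueError("n_yield must be >= 0")
    n_content_g_kg = n_yield / dm_yield  # kg/ha over t/ha -> g/kg
    return 6.25 * n_content_g_kg


def milk_per_cow_per_day(milk_yield_t_ha: float, stocking_rate: float) -> float:
    """Convert an areal milk yield (t ECM/ha/yr) to kg ECM per animal per day.

    All per-animal <-> per-hectare conversions in the pipeline route through
    the stocking rate (LU/ha); this helper is the only place that
    arithmetic lives.
    """
    _check_finite_positive("stocking_rate", stocking_rate)
    return milk_yield_t_ha * 1000.0 / stocking_rate / DAYS_PER_YEAR


def estimate_dm_intake(
    milk_yield_per_cow: float,
    live_weight: float,
    supplement: float,
    coeffs: IntakeCoefficients | None = None,
    herbage_cp: float = 0.0,
    supplement_cp: float = 0.0,
) -> IntakeProfile:
    """Daily feed intake of one cow, split into pasture and concentrate.

    DMI = lw_coeff*LW + milk_coeff*milk + intercept (kg DM/day); pasture
    intake is the remainder after the fixed concentrate allowance.  The
    default coefficients place a 380 kg Jersey cow at herd-average milk
    yield in the 14-15 kg DM/day band.  Crude-protein intake is computed
    from the component CP contents (g/kg DM) when supplied.
    """
    coeffs = coeffs or IntakeCoefficients()
    for name, value in (("milk_yield_per_cow", milk_yield_per_cow),
                        ("live_weight", live_weight), ("supplement", supplement)):
        if value < 0 or not math.isfinite(value):
            raise ValueError(f"{name} must be finite and >= 0, got {value}")
    total = (coeffs.lw_coeff * live_weight
             + coeffs.milk_coeff * milk_yield_per_cow
             + coeffs.intercept)
    pasture = total - supplement
    if pasture < 0:
        raise ValueError(
            f"supplement allowance {supplement} kg exceeds total intake {total:.1f} kg"
        )
    cp_intake = pasture * herbage_cp + supplement * supplement_cp
    diet_cp = cp_intake / total if total > 0 else 0.0
    return IntakeProfile(
        dm_intake_total=total,
        dm_intake_pasture=pasture,
        dm_intake_supplement=supplement,
        cp_intake=cp_intake,
        diet_cp_content=diet_cp,
    )


def intake_for_treatment(
    milk_yield_t_ha: float,
    herd: HerdParameters,
    constants: ModelConstants,
    herbage_cp: float,
) -> IntakeProfile:
    """Intake profile of one treatment-year from its areal milk yield."""
    if herd.supplement_cp_content is None:
        warnings.warn("supplement CP content not calibrated; assuming 180 g/kg")
    supplement_cp = herd.supplement_cp_content or 180.0
    milk_cow = milk_per_cow_per_day(milk_yield_t_ha, herd.stocking_rate)
    return estimate_dm_intake(
        milk_cow,
        herd.live_weight,
        herd.supplement_dm_per_day,
        coeffs=constants.intake_model,
        herbage_cp=herbage_cp,
        supplement_cp=supplement_cp,
    )
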