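"""Stage 3: per-hectare greenhouse-gas inventory in CO2 equivalents.

Line items (all kg CO2eq/ha/yr):

* enteric CH4 from ruminal fermentation (yield per kg DM intake),
* direct soil N2O from the field-N-balance via an exponential response,
* indirect N2O from volatilized NH3 and leached N,
* embodied emissions of fertilizer, seeds and grassland renovation,
* field operations (fertilizer dressings, mulching),
* concentrate feed production,
* irrigation energy, milking and shed operation,
* manure storage (slurry handling plus storage CH4),
* and a negative soil-organic-carbon offset.

Gas-species bookkeeping: N2O-N <-> N2O via 44/28, C <-> CO2 via 44/12;
mass-to-CO2eq conversion uses GWP100 factors (N2O x 265, CH4 x 28).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .forage_energy import IntakeProfile
from .scenario_model import (
    EmissionFactorTable,
    ManureStorageParams,
    MethaneCoefficients,
    ModelConstants,
    SocModelParams,
)

__all__ = [
    "GhgInventory",
    "n2o_direct",
    "n2o_n_direct",
    "n2o_indirect",
    "enteric_ch4",
    "embodied_inputs",
    "irrigation_emissions",
    "management_emissions",
    "manure_storage_emissions",
    "soc_change",
    "aggregate_gwp",
]

N2O_N_TO_N2O = 44.0 / 28.0
C_TO_CO2 = 44.0 / 12.0
#: Plausibility band for annual per-cow enteric CH4, kg/yr.
CH4_SANITY_BAND = (60.0, 160.0)


@dataclass
class GhgInventory:
    """Per-hectare annual emission line items, kg CO2eq/ha/yr.

    All items except ``soc_offset`` are nonnegative; ``soc_offset`` is the
    (negative) soil-carbon credit.
    """

    enteric_ch4: float = 0.0
    pasture_n2o_direct: float = 0.0
    pasture_n2o_indirect: float = 0.0
    fertilizer_embodied: float = 0.0
    seeds_and_renovation: float = 0.0
    field_operations: float = 0.0
    supplement_feed: float = 0.0
    irrigation_energy: float = 0.0
    manure_storage: float = 0.0
    milking_shed: float = 0.0
    soc_offset: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "soc_offset":
                if value > 0:
                    raise ValueError("soc_offset must be <= 0 (a credit)")
            elif value < 0:
                raise ValueError(f"{f.name} must be >= 0")

    @property
    def gwp_gross(self) -> float:
        """Sum of all emission items excluding the SOC credit, kg CO2eq/ha."""
        return sum(getattr(self, f.name) for f in fields(self)
                   if f.name != "soc_offset")

    @property
    def gwp_net(self) -> float:
        return self.gwp_gross + self.soc_offset

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __add__(self, other: "GhgInventory") -> "GhgInventory":
        return GhgInventory(**{
            f.name: getattr(self, f.name) + getattr(other, f.name)
            for f in fields(self)
        })

    def scaled(self, factor: float) -> "GhgInventory":
        return GhgInventory(**{f.name: getattr(self, f.name) * factor
                               for f in fields(self)})


def n2o_direct(field_balance: float, intercept: float = 1.99,
               scale: float = 1.39, rate: float = 0.00488) -> float:
    """Soil N2O emission from the field-N-balance, kg N2O/ha/yr.

    Exponential response ``intercept + scale * exp(rate * x)``: strictly
    increasing and convex in the surplus x, bounded below by the intercept
    (a background emission persists even under strongly negative balances).
    """
    if not math.isfinite(field_balance):
        raise ValueError("field_balance must be finite")
    return intercept + scale * math.exp(rate * field_balance)


def n2o_n_direct(field_balance: float, constants: ModelConstants) -> tuple[float, float]:
    """Direct soil N2O as (kg N2O/ha, kg N2O-N/ha) under the configured reading.

    The response function's output species is configurable: by default its
    value is kg N2O; the alternative reading treats it as kg N2O-N.
    """
    value = n2o_direct(field_balance, constants.n2o_intercept,
                       constants.n2o_scale, constants.n2o_rate)
    if constants.n2o_output_species == "n2o":
        return value, value / N2O_N_TO_N2O
    return value * N2O_N_TO_N2O, value


def n2o_indirect(nh3_n: float, leached: float,
                 ef_volat: float = 0.01, ef_leach: float = 0.011) -> float:
    """Indirect N2O from redeposited NH3 and leached N, kg N2O/ha/yr."""
    for name, value in (("nh3_n", nh3_n), ("leached", leached)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    for name, value in (("ef_volat", ef_volat), ("ef_leach", ef_leach)):
        if not (0.0 <= value <= 0.1):
            raise ValueError(f"{name} must be in [0, 0.1], got {value}")
    return (nh3_n * ef_volat + leached * ef_leach) * N2O_N_TO_N2O


def enteric_ch4(intake: IntakeProfile, stocking_rate: float,
                coeffs: MethaneCoefficients | None = None) -> float:
    """Enteric methane, kg CH4/ha/yr.

    Separate methane yields (g CH4 per kg DM) apply to the herbage and
    concentrate intake components; per-cow emissions scale to the hectare
    through the stocking rate.  Per-cow annual CH4 outside 60-160 kg is
    flagged with a warning.
    """
    if stocking_rate < 0:
        raise ValueError("stocking_rate must be >= 0")
    coeffs = coeffs or MethaneCoefficients()
    herbage_y, conc_y = coeffs.scaled()
    per_cow_day_g = (intake.dm_intake_pasture * herbage_y
                     + intake.dm_intake_supplement * conc_y)
    per_cow_year_kg = per_cow_day_g * 365.0 / 1000.0
    lo, hi = CH4_SANITY_BAND
    if intake.dm_intake_total > 0 and not (lo <= per_cow_year_kg <= hi):
        warnings.warn(
            f"per-cow enteric CH4 {per_cow_year_kg:.0f} kg/yr outside the "
            f"plausible [{lo:.0f}, {hi:.0f}] band", stacklevel=2,
        )
    return per_cow_year_kg * stocking_rate


def embodied_inputs(n_rate: float, ef: EmissionFactorTable,
                    renovation_interval: int | None = None,
                    seed_rate: float = 25.0,
                    dressings: int = 12,
                    mulching_passes: int = 1) -> dict[str, float]:
    """Embodied input and field-operation emissions, kg CO2eq/ha/yr.

    Returns the three inventory contributions separately:

    * ``fertilizer_embodied`` - manufacture of the fertilizer N applied;
    * ``seeds_and_renovation`` - seed production plus tillage and sowing,
      annualized over the renovation interval;
    * ``field_operations`` - yearly fertilizer dressings (only when N is
      applied) and mulching passes.
    """
    if n_rate < 0:
        raise ValueError("n_rate must be >= 0")
    interval = renovation_interval or ef.renovation_interval_years
    fertilizer = n_rate * ef.factor("ammonium_nitrate_n")
    renovation = (
        ef.factor("tillage") + ef.factor("sowing")
        + seed_rate * ef.factor("grass_seeds")
    ) / interval
    dressings_applied = dressings if n_rate > 0 else 0
    operations = (dressings_applied * ef.factor("fertilizing_broadcaster")
                  + mulching_passes * ef.factor("mulching"))
    return {
        "fertilizer_embodied": fertilizer,
        "seeds_and_renovation": renovation,
        "field_operations": operations,
    }


def irrigation_emissions(volume: float, ef: EmissionFactorTable | float) -> float:
    """Irrigation energy emissions, kg CO2eq/ha/yr."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    factor = ef.factor("irrigation") if isinstance(ef, EmissionFactorTable) else float(ef)
    return volume * factor


def management_emissions(milk_yield: float, stocking_rate: float,
                         ef: EmissionFactorTable,
                         shed_fraction: float) -> float:
    """Milking-parlor and shed-operation emissions, kg CO2eq/ha/yr.

    The shed-operation factor is quoted per LU for full housing; only the
    non-grazing share of the year (``shed_fraction``) is charged.
    """
    if milk_yield < 0 or stocking_rate < 0:
        raise ValueError("inputs must be >= 0")
    if not (0.0 <= shed_fraction <= 1.0):
        raise ValueError("shed_fraction must be in [0, 1]")
    milking = milk_yield * 1000.0 * ef.factor("milking")
    shed = stocking_rate * ef.factor("shed_operation") * shed_fraction
    return milking + shed


def manure_storage_emissions(intake: IntakeProfile, stocking_rate: float,
                             ef: EmissionFactorTable,
                             params: ManureStorageParams,
                             shed_fraction: float,
                             gwp_ch4: float = 28.0) -> float:
    """Slurry handling plus storage CH4 for housed-time manure, kg CO2eq/ha/yr."""
    if not (0.0 <= shed_fraction <= 1.0):
        raise ValueError("shed_fraction must be in [0, 1]")
    slurry_m3 = stocking_rate * shed_fraction * 365.0 * params.slurry_m3_per_lu_day
    slurry = slurry_m3 * ef.factor("slurry_store")
    ch4_kg = (intake.dm_intake_total * shed_fraction * 365.0
              * params.manure_ch4_yield / 1000.0) * stocking_rate
    return slurry + ch4_kg * gwp_ch4


def soc_change(dm_yield: float, params: SocModelParams) -> tuple[float, float]:
    """Annual soil-carbon sequestration and its CO2eq credit.

    Returns ``(sequestration_kg_c_ha, offset_kg_co2eq_ha)`` with the offset
    negative (= -sequestration x 44/12).  ``dm_yield`` in t DM/ha.
    """
    if dm_yield <= 0:
        raise ValueError("dm_yield must be positive")
    retention = params.retention_coefficient
    if retention is None:
        raise ValueError("soc retention_coefficient not calibrated")
    c_input = dm_yield * 1000.0 * params.herbage_c_content * params.root_c_fraction
    sequestration = c_input * retention
    return sequestration, -sequestration * C_TO_CO2


def aggregate_gwp(ch4_mass: float = 0.0, n2o_mass: float = 0.0,
                  co2_mass: float = 0.0, soc_offset: float = 0.0,
                  gwp_ch4: float = 28.0, gwp_n2o: float = 265.0) -> tuple[float, float]:
    """GWP100 aggregation of gas masses, kg CO2eq (gross, net).

    ``net`` adds the (negative) soil-carbon offset to the gross total.
    """
    for name, value in (("ch4_mass", ch4_mass), ("n2o_mass", n2o_mass),
                        ("co2_mass", co2_mass)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    gross = ch4_mass * gwp_ch4 + n2o_mass * gwp_n2o + co2_mass
    return gross, gross + soc_offset


def n2o_response_curve(balances: np.ndarray, constants: ModelConstants) -> np.ndarray:
    """Vectorized direct-N2O response, used for grid diagnostics."""
    x = np.asarray(balances, dtype=float)
    return constants.n2o_intercept + constants.n2o_scale * np.exp(constants.n2o_rate * x)
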