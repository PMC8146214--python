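"""Stage 4: per-treatment footprints, contribution shares and relationships.

This module chains the three computation stages over each treatment-year,
averages across years, and expresses the results per unit product: the
carbon footprint (kg CO2eq per kg energy-corrected milk), the nitrogen
footprint (g reactive N lost per kg ECM) and the land requirement.  It
also fits the cross-treatment relationships between the farm-N-balance,
areal GHG emissions and milk yield.

The carbon footprint is aggregated as the mean of yearly ratios (each
year's net GWP over that year's milk), not the ratio of three-year means;
both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import forage_energy, ghg_inventory, nitrogen_cycle
from .forage_energy import IntakeProfile, MilkEnergyRequirement
from .ghg_inventory import GhgInventory, N2O_N_TO_N2O
from .nitrogen_cycle import NitrogenBalance
from .scenario_model import HerbageYearRecord, MethaneCoefficients, SocModelParams, TreatmentScenario

__all__ = [
    "FootprintResult",
    "YearResult",
    "TreatmentResult",
    "carbon_footprint",
    "land_requirement",
    "contribution_shares",
    "relationship_fits",
    "evaluate_scenario",
    "evaluate_scenarios",
]


@dataclass
class FootprintResult:
    """Farm-gate efficiency metrics for one treatment (three-year level)."""

    treatment_id: str
    milk_yield: float               # t ECM/ha/yr, mean over years
    gwp_gross: float                # t CO2eq/ha/yr
    gwp_net: float                  # t CO2eq/ha/yr, incl. SOC offset
    cf_net: float                   # kg CO2eq/kg ECM, mean of yearly ratios
    cf_net_ratio_of_means: float
    n_footprint: float              # g N/kg ECM
    land_requirement: float         # m2 per kg ECM
    soc_sequestration: float        # t C/ha/yr
    shares: dict[str, float] = field(default_factory=dict)  # % of gwp_gross


@dataclass
class YearResult:
    year_index: int
    milk_yield: float               # t ECM/ha
    intake: IntakeProfile
    balance: NitrogenBalance
    inventory: GhgInventory
    soc_sequestration_kg_c: float
    cf_net: float                   # kg CO2eq/kg ECM
    n_footprint: float              # g N/kg ECM


@dataclass
class TreatmentResult:
    treatment_id: str
    years: list[YearResult]
    balance: NitrogenBalance        # means of yearly ledger items
    inventory: GhgInventory         # means of yearly line items
    footprint: FootprintResult


def carbon_footprint(yearly_gwp_net: list[float], yearly_milk: list[float],
                     method: str = "mean_of_ratios") -> float:
    """Carbon footprint, kg CO2eq per kg ECM.

    ``yearly_gwp_net`` in t CO2eq/ha, ``yearly_milk`` in t ECM/ha; the t/t
    ratio is numerically kg/kg.  ``method`` selects mean-of-yearly-ratios
    (default) or ratio-of-means.
    """
    gwp = np.asarray(yearly_gwp_net, dtype=float)
    milk = np.asarray(yearly_milk, dtype=float)
    if gwp.shape != milk.shape or gwp.size == 0:
        raise ValueError("need equal-length, non-empty yearly series")
    if np.any(milk <= 0):
        raise ValueError("milk yield must be positive in every year")
    if method == "mean_of_ratios":
        return float(np.mean(gwp / milk))
    if method == "ratio_of_means":
        return float(np.mean(gwp) / np.mean(milk))
    raise ValueError(f"unknown method {method!r}")


def land_requirement(milk_yield: float) -> float:
    """Pasture area needed per kg ECM, m2/kg (10,000 m2 over kg/ha)."""
    if milk_yield <= 0:
        raise ValueError("milk_yield must be positive")
    return 10_000.0 / (milk_yield * 1000.0)


def contribution_shares(inventory: GhgInventory) -> dict[str, float]:
    """Each non-SOC line item as % of the gross GWP; sums to 100."""
    gross = inventory.gwp_gross
    if gross <= 0:
        raise ValueError("gross GWP must be positive")
    return {
        name: value / gross * 100.0
        for name, value in inventory.as_dict().items()
        if name != "soc_offset"
    }


# ---------------------------------------------------------------------------
# per-treatment evaluation chain

def evaluate_year(scenario: TreatmentScenario, record: HerbageYearRecord,
                  calib) -> YearResult:
    """Run all three stages for one treatment-year."""
    herd, constants = scenario.herd, scenario.constants
    ef = scenario.emission_factors

    req = MilkEnergyRequirement.from_composition(herd.milk_fat_pct,
                                                 herd.milk_protein_pct)
    milk = forage_energy.potential_milk_yield(record.energy_yield, req,
                                              calib.utilization)
    if constants.milk_grazing_adjustment:
        milk *= constants.grazing_proportion

    herbage_cp = forage_energy.herbage_cp_content(record.n_yield, record.dm_yield)
    milk_cow = forage_energy.milk_per_cow_per_day(milk, herd.stocking_rate)
    intake = forage_energy.estimate_dm_intake(
        milk_cow, herd.live_weight, herd.supplement_dm_per_day,
        coeffs=constants.intake_model,
        herbage_cp=herbage_cp,
        supplement_cp=calib.supplement_cp_content,
    )

    # --- nitrogen chain (kg N/ha) ---
    milk_n = nitrogen_cycle.milk_n_export(milk, herd.milk_protein_pct,
                                          constants.milk_n_divisor)
    herbage_n = record.n_yield * constants.pasture_utilization_fraction
    n_intake_total = herbage_n + calib.supplement_n_per_ha
    excreta = nitrogen_cycle.excreta_n(n_intake_total, milk_n,
                                       constants.grazing_proportion)
    nh3 = nitrogen_cycle.nh3_loss(excreta, constants.tan_fraction_of_excreta,
                                  constants.tan_emission_factor)
    field = nitrogen_cycle.field_n_balance(scenario.n_fertilizer_rate, excreta,
                                           nh3, herbage_n)
    leach = nitrogen_cycle.leached_n(field, constants.frac_leach)
    farm = nitrogen_cycle.farm_n_balance(scenario.n_fertilizer_rate,
                                         calib.supplement_n_per_ha, milk_n,
                                         constants.meat_n_export)

    n2o_mass, n2o_n = ghg_inventory.n2o_n_direct(field, constants)
    n2o_ind_mass = ghg_inventory.n2o_indirect(
        nh3, leach, constants.ef_volatilization_n2o, constants.ef_leaching_n2o)
    n2o_ind_n = n2o_ind_mass / N2O_N_TO_N2O

    balance = NitrogenBalance(
        fertilizer_n_in=scenario.n_fertilizer_rate,
        supplement_n_in=calib.supplement_n_per_ha,
        excreta_n_returned=excreta,
        herbage_n_yield=herbage_n,
        milk_n_out=milk_n,
        meat_n_out=constants.meat_n_export,
        nh3_n_loss=nh3,
        leached_n=leach,
        field_balance=field,
        farm_balance=farm,
        n2o_n_loss=n2o_n + n2o_ind_n,
    )

    # --- GHG inventory (kg CO2eq/ha) ---
    shed_fraction = 1.0 - constants.grazing_proportion
    methane = MethaneCoefficients(
        herbage_yield=constants.methane_model.herbage_yield,
        concentrate_yield=constants.methane_model.concentrate_yield,
        scale=calib.ch4_scale,
    )
    ch4_kg = ghg_inventory.enteric_ch4(intake, herd.stocking_rate, methane)
    embodied = ghg_inventory.embodied_inputs(
        scenario.n_fertilizer_rate, ef,
        renovation_interval=constants.renovation_interval_years,
        seed_rate=constants.seed_rate_kg_ha,
        dressings=scenario.dressings_per_year,
        mulching_passes=constants.mulching_passes_per_year,
    )
    supplement_dm_ha = (herd.supplement_dm_per_day * herd.cows * 365.0
                        / herd.farm_area)
    soc_params = SocModelParams(
        herbage_c_content=constants.soc_model.herbage_c_content,
        root_c_fraction=constants.soc_model.root_c_fraction,
        retention_coefficient=calib.soc_retention,
    )
    sequestration, soc_offset = ghg_inventory.soc_change(record.dm_yield, soc_params)

    inventory = GhgInventory(
        enteric_ch4=ch4_kg * constants.gwp_ch4,
        pasture_n2o_direct=n2o_mass * constants.gwp_n2o,
        pasture_n2o_indirect=n2o_ind_mass * constants.gwp_n2o,
        fertilizer_embodied=embodied["fertilizer_embodied"],
        seeds_and_renovation=embodied["seeds_and_renovation"],
        field_operations=embodied["field_operations"],
        supplement_feed=supplement_dm_ha * constants.supplement_emission_factor,
        irrigation_energy=ghg_inventory.irrigation_emissions(
            constants.irrigation_volume, ef),
        manure_storage=ghg_inventory.manure_storage_emissions(
            intake, herd.stocking_rate, ef, constants.manure_storage,
            shed_fraction, constants.gwp_ch4),
        milking_shed=ghg_inventory.management_emissions(
            milk, herd.stocking_rate, ef, shed_fraction),
        soc_offset=soc_offset,
    )

    cf_net = inventory.gwp_net / 1000.0 / milk  # t CO2eq / t ECM == kg/kg
    n_fp = nitrogen_cycle.n_footprint(nh3, leach, n2o_n + n2o_ind_n, milk)
    return YearResult(
        year_index=record.year_index,
        milk_yield=milk,
        intake=intake,
        balance=balance,
        inventory=inventory,
        soc_sequestration_kg_c=sequestration,
        cf_net=cf_net,
        n_footprint=n_fp,
    )


def _mean_balance(years: list[YearResult]) -> NitrogenBalance:
    n = len(years)

    def mean(attr: str) -> float:
        return sum(getattr(y.balance, attr) for y in years) / n

    return NitrogenBalance(**{
        name: mean(name)
        for name in ("fertilizer_n_in", "supplement_n_in", "excreta_n_returned",
                     "herbage_n_yield", "milk_n_out", "meat_n_out", "nh3_n_loss",
                     "leached_n", "field_balance", "farm_balance", "n2o_n_loss")
    })


def evaluate_scenario(scenario: TreatmentScenario, calib) -> TreatmentResult:
    """Full pipeline for one treatment: yearly results plus three-year means."""
    years = [evaluate_year(scenario, record, calib)
             for record in sorted(scenario.years, key=lambda r: r.year_index)]
    n = len(years)
    mean_inventory = years[0].inventory
    for y in years[1:]:
        mean_inventory = mean_inventory + y.inventory
    mean_inventory = mean_inventory.scaled(1.0 / n)

    milk_years = [y.milk_yield for y in years]
    net_years_t = [y.inventory.gwp_net / 1000.0 for y in years]
    mean_milk = float(np.mean(milk_years))

    footprint = FootprintResult(
        treatment_id=scenario.treatment_id,
        milk_yield=mean_milk,
        gwp_gross=mean_inventory.gwp_gross / 1000.0,
        gwp_net=mean_inventory.gwp_net / 1000.0,
        cf_net=carbon_footprint(net_years_t, milk_years, "mean_of_ratios"),
        cf_net_ratio_of_means=carbon_footprint(net_years_t, milk_years,
                                               "ratio_of_means"),
        n_footprint=float(np.mean([y.n_footprint for y in years])),
        land_requirement=land_requirement(mean_milk),
        soc_sequestration=float(np.mean([y.soc_sequestration_kg_c for y in years]))
        / 1000.0,
        shares=contribution_shares(mean_inventory),
    )
    return TreatmentResult(
        treatment_id=scenario.treatment_id,
        years=years,
        balance=_mean_balance(years),
        inventory=mean_inventory,
        footprint=footprint,
    )


def evaluate_scenarios(scenarios: list[TreatmentScenario],
                       calib) -> list[TreatmentResult]:
    return [evaluate_scenario(s, calib)
            for s in sorted(scenarios, key=lambda s: s.n_fertilizer_rate)]


# ---------------------------------------------------------------------------
# cross-treatment relationships

def _fit_linear(x: np.ndarray, y: np.ndarray) -> dict:
    coeffs = np.polyfit(x, y, 1)
    residuals = y - np.polyval(coeffs, x)
    return {"slope": float(coeffs[0]), "intercept": float(coeffs[1]),
            "rss": float(np.sum(residuals ** 2))}


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> dict:
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive responses")
    # log-linear start values keep curve_fit away from the flat region
    b0, log_a0 = np.polyfit(x, np.log(y), 1)

    def model(x, a, b):
        return a * np.exp(b * x)

    params, _ = curve_fit(model, x, y, p0=(np.exp(log_a0), b0), maxfev=20000)
    residuals = y - model(x, *params)
    return {"a": float(params[0]), "b": float(params[1]),
            "rss": float(np.sum(residuals ** 2))}


def relationship_fits(farm_balances: list[float], gwp_values: list[float],
                      milk_values: list[float]) -> dict:
    """Fit GWP and milk yield against the farm-N-balance.

    Returns linear and exponential least-squares fits for each response,
    with residual sums of squares, so the shape of each relationship
    (exponential for areal GHG, linear for milk) can be compared.
    """
    x = np.asarray(farm_balances, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three treatments to fit relationships")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) farm balances")
    out = {}
    for name, values in (("gwp", gwp_values), ("milk", milk_values)):
        y = np.asarray(values, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"degenerate (constant) {name} values")
        out[name] = {"linear": _fit_linear(x, y),
                     "exponential": _fit_exponential(x, y)}
    out["gwp_exponential_preferred"] = (
        out["gwp"]["exponential"]["rss"] < out["gwp"]["linear"]["rss"])
    out["milk_linear_preferred"] = (
        out["milk"]["linear"]["rss"] < out["milk"]["exponential"]["rss"])
    return out
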