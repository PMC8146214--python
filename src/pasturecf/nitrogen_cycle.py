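"""Stage 2: nitrogen intake, excretion, losses and the two N balances.

Two balances are tracked per treatment-year:

* field-N-balance (paddock scale): fertilizer N plus excreta N returned
  during grazing (net of ammonia volatilization) minus the N removed in
  herbage.  A positive surplus drives leaching and the soil N2O response.
* farm-N-balance (farm gate): fertilizer and purchased-feed N imports
  minus milk and meat N exports.  Gaseous losses are deliberately not
  deducted at this scale.

Excreted N is diet N intake (herbage plus concentrate) minus milk N; the
fraction deposited on pasture is the annual grazing-day proportion (0.83).
Ammonia losses apply an emission factor to the total ammoniacal N (TAN)
share of excreta.  The N-footprint divides the summed reactive-N losses
(NH3-N, leached N, N2O-N) by the milk yield.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .forage_energy import IntakeProfile
from .scenario_model import ExcretionCoefficients

__all__ = [
    "NitrogenBalance",
    "milk_n_export",
    "excreta_n",
    "nex_per_cow",
    "nh3_loss",
    "leached_n",
    "field_n_balance",
    "farm_n_balance",
    "n_footprint",
]

#: Plausibility band for per-cow daily N excretion, g N/day.
NEX_SANITY_BAND = (150.0, 600.0)


@dataclass
class NitrogenBalance:
    """Field- and farm-scale N ledger for one treatment (kg N/ha/yr)."""

    fertilizer_n_in: float
    supplement_n_in: float
    excreta_n_returned: float
    herbage_n_yield: float
    milk_n_out: float
    meat_n_out: float
    nh3_n_loss: float
    leached_n: float
    field_balance: float
    farm_balance: float
    n2o_n_loss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nh3_n_loss", "leached_n", "n2o_n_loss", "milk_n_out",
                     "meat_n_out", "excreta_n_returned"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        expected_farm = (self.fertilizer_n_in + self.supplement_n_in
                         - self.milk_n_out - self.meat_n_out)
        if abs(self.farm_balance - expected_farm) > 1e-6:
            raise ValueError("farm_balance inconsistent with its ledger items")
        expected_field = (self.fertilizer_n_in + self.excreta_n_returned
                          - self.nh3_n_loss - self.herbage_n_yield)
        if abs(self.field_balance - expected_field) > 1e-6:
            raise ValueError("field_balance inconsistent with its ledger items")


def milk_n_export(milk_yield: float, protein_pct: float,
                  milk_n_divisor: float = 6.38) -> float:
    """N exported in milk, kg N/ha: protein yield divided by 6.38.

    ``milk_yield`` in t ECM/ha, ``protein_pct`` in percent.
    """
    for name, value in (("milk_yield", milk_yield), ("protein_pct", protein_pct)):
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {value}")
    protein_kg_ha = milk_yield * 1000.0 * protein_pct / 100.0
    return protein_kg_ha / milk_n_divisor


def excreta_n(n_intake: float, milk_n: float, grazing_proportion: float) -> float:
    """Excreta N deposited on pasture, kg N/ha.

    Diet N not captured in milk is excreted; the share of the year spent
    grazing determines how much lands on the paddock.
    """
    if not (0.0 <= grazing_proportion <= 1.0):
        raise ValueError("grazing_proportion must be in [0, 1]")
    if milk_n < 0:
        raise ValueError("milk_n must be >= 0")
    if milk_n > n_intake:
        raise ValueError(
            f"infeasible scenario: milk N ({milk_n:.1f}) exceeds N intake "
            f"({n_intake:.1f})"
        )
    return (n_intake - milk_n) * grazing_proportion


def nex_per_cow(intake: IntakeProfile, live_weight: float,
                coeffs: ExcretionCoefficients | None = None,
                cp_factor: float = 6.25) -> float:
    """Daily N excretion of one cow, g N/day.

    Nex = excreted_fraction x N intake + lw_coeff x LW + intercept, where
    N intake (g/day) is CP intake / 6.25.  Values outside the
    150-600 g/day band for a lactating cow are flagged with a warning.
    """
    if live_weight <= 0:
        raise ValueError("live_weight must be positive")
    coeffs = coeffs or ExcretionCoefficients()
    n_intake_g = intake.cp_intake / cp_factor
    nex = (coeffs.excreted_fraction * n_intake_g
           + coeffs.lw_coeff * live_weight
           + coeffs.intercept)
    lo, hi = NEX_SANITY_BAND
    if intake.cp_intake > 0 and not (lo <= nex <= hi):
        warnings.warn(
            f"daily N excretion {nex:.0f} g outside the plausible "
            f"[{lo:.0f}, {hi:.0f}] g/day band", stacklevel=2,
        )
    return nex


def nh3_loss(excreta_n_value: float, tan_fraction: float, tan_ef: float) -> float:
    """NH3-N volatilized from pasture excreta, kg N/ha.

    ``tan_fraction`` is the TAN share of excreted N; ``tan_ef`` the
    emission factor applied to TAN.
    """
    for name, value in (("tan_fraction", tan_fraction), ("tan_ef", tan_ef)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    if excreta_n_value < 0:
        raise ValueError("excreta_n must be >= 0")
    return excreta_n_value * tan_fraction * tan_ef


def leached_n(field_surplus: float, frac_leach: float) -> float:
    """N leached below the root zone, kg N/ha.

    Only positive field surpluses leach; a deficit is clipped to zero
    rather than producing a negative loss.
    """
    if not (0.0 <= frac_leach <= 1.0):
        raise ValueError("frac_leach must be in [0, 1]")
    return max(0.0, field_surplus) * frac_leach


def field_n_balance(fertilizer_n: float, excreta_returned: float,
                    nh3_n: float, herbage_n_yield: float) -> float:
    """Paddock-scale N balance, kg N/ha (may be negative).

    Inputs are fertilizer N and excreta returns net of ammonia
    volatilization; the output is the N harvested in herbage.
    """
    return fertilizer_n + (excreta_returned - nh3_n) - herbage_n_yield


def farm_n_balance(fertilizer_n: float, supplement_n: float,
                   milk_n: float, meat_n: float) -> float:
    """Farm-gate N balance, kg N/ha: imports minus product exports.

    Gaseous N losses are not deducted at the farm gate.
    """
    for name, value in (("fertilizer_n", fertilizer_n), ("supplement_n", supplement_n),
                        ("milk_n", milk_n), ("meat_n", meat_n)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    return fertilizer_n + supplement_n - milk_n - meat_n


def n_footprint(nh3_n: float, leached: float, n2o_n: float,
                milk_yield: float) -> float:
    """Reactive-N losses per unit product, g N per kg ECM.

    ``milk_yield`` in t ECM/ha; loss terms in kg N/ha.  kg N per t ECM is
    numerically g N per kg ECM.
    """
    if milk_yield <= 0:
        raise ValueError("milk_yield must be positive")
    for name, value in (("nh3_n", nh3_n), ("leached", leached), ("n2o_n", n2o_n)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    return (nh3_n + leached + n2o_n) / milk_yield


def supplement_n_per_ha(supplement_cp: float, supplement_dm_per_day: float,
                        cows: float, farm_area: float,
                        cp_factor: float = 6.25) -> float:
    """Concentrate N import, kg N/ha/yr, from its CP content (g CP/kg DM)."""
    if supplement_cp < 0:
        raise ValueError("supplement_cp must be >= 0")
    n_per_kg = supplement_cp / cp_factor          # g N per kg DM
    g_per_year = n_per_kg * supplement_dm_per_day * cows * 365.0
    return g_per_year / farm_area / 1000.0
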