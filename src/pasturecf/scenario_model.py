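"""Domain types, model constants and packaged trial data.

This module holds every record type the pipeline passes between stages:
per-year herbage records, herd parameters, model constants, the emission
factor table, and the :class:`TreatmentScenario` container that bundles one
fertilization treatment's full driving data.  It also loads the packaged
fixtures: the three-year herbage table for the five N treatments (N0, N20,
N40, N60, N80 = 0, 220, 440, 660, 880 kg N ha-1 yr-1), the emission-factor
table, and the published reference values used for calibration/validation.

Units are SI-based internally (kg, kg N and MJ per hectare per year); t DM
and GJ NEL appear only at I/O boundaries, mirroring how the driving data
are tabulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "HerbageYearRecord",
    "HerdParameters",
    "IntakeCoefficients",
    "ExcretionCoefficients",
    "MethaneCoefficients",
    "SocModelParams",
    "ManureStorageParams",
    "ModelConstants",
    "EmissionFactorTable",
    "TreatmentScenario",
    "average_over_years",
    "load_paper_fixtures",
    "load_reference",
    "load_constants",
    "load_emission_factors",
]

#: Field labels accepted by :func:`average_over_years`.
YIELD_FIELDS = ("dm_yield", "n_yield", "energy_yield")


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass
class HerbageYearRecord:
    """One pasture-year of measured herbage supply.

    Parameters
    ----------
    treatment_id : str
        Treatment label (``N0`` ... ``N80``).
    year_index : int
        Experimental year (1-3).
    dm_yield : float
        Total herbage production, t DM ha-1 yr-1.
    n_yield : float
        Herbage nitrogen yield, kg N ha-1 yr-1.
    energy_yield : float
        Net-energy-lactation yield, GJ NEL ha-1 yr-1.
    sem_dm, sem_n, sem_energy : float, optional
        Standard errors of the mean in the same units; stored for the
        synthetic-data generator only, the deterministic pipeline never
        reads them.
    """

    treatment_id: str
    year_index: int
    dm_yield: float
    n_yield: float
    energy_yield: float
    sem_dm: float | None = None
    sem_n: float | None = None
    sem_energy: float | None = None

    def __post_init__(self) -> None:
        tag = f"{self.treatment_id} year {self.year_index}"
        _require(self.year_index >= 1, f"{tag}: year_index must be >= 1")
        for name in YIELD_FIELDS:
            value = getattr(self, name)
            _require(
                isinstance(value, (int, float)) and math.isfinite(value) and value > 0,
                f"{tag}: {name} must be a positive finite number, got {value!r}",
            )
        n_content = self.n_yield / (self.dm_yield * 1000.0)
        _require(
            n_content <= 0.06,
            f"{tag}: herbage N content {n_content:.3f} exceeds 6% of DM",
        )
        energy_density = self.energy_yield * 1000.0 / (self.dm_yield * 1000.0)
        _require(
            4.0 <= energy_density <= 9.0,
            f"{tag}: energy density {energy_density:.2f} MJ NEL/kg DM outside [4, 9]",
        )

    @property
    def n_content_g_kg(self) -> float:
        """Herbage N content, g N per kg DM."""
        return self.n_yield / self.dm_yield  # kg/ha over t/ha == g/kg


@dataclass
class HerdParameters:
    """Herd and farm parameters shared by all treatments."""

    milk_fat_pct: float = 4.9
    milk_protein_pct: float = 3.7
    live_weight: float = 380.0
    stocking_rate: float = 4.7
    cows: int = 454
    farm_area: float = 121.0
    replacement_rate: float = 0.25
    supplement_dm_per_day: float = 3.2
    supplement_cp_content: float | None = None  # g CP/kg DM, calibrated

    def __post_init__(self) -> None:
        for name in ("milk_fat_pct", "milk_protein_pct"):
            value = getattr(self, name)
            _require(0 < value < 100, f"{name} must be in (0, 100), got {value}")
        _require(0 < self.replacement_rate < 1, "replacement_rate must be in (0, 1)")
        for name in ("live_weight", "stocking_rate", "cows", "farm_area",
                     "supplement_dm_per_day"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        if self.supplement_cp_content is not None:
            _require(self.supplement_cp_content > 0,
                     "supplement_cp_content must be positive when set")

    @property
    def cows_per_ha(self) -> float:
        return self.cows / self.farm_area


@dataclass
class IntakeCoefficients:
    """Linear daily DM-intake model: DMI = lw_coeff*LW + milk_coeff*milk + intercept."""

    lw_coeff: float = 0.02
    milk_coeff: float = 0.28
    intercept: float = 4.0


@dataclass
class ExcretionCoefficients:
    """Daily N excretion: Nex = excreted_fraction*N_intake + lw_coeff*LW + intercept (g/day)."""

    excreted_fraction: float = 0.84
    lw_coeff: float = 0.0
    intercept: float = 0.0


@dataclass
class MethaneCoefficients:
    """Enteric CH4 yields in g CH4 per kg DM intake, by feed component.

    ``scale`` multiplies both yields; it is the single calibrated closure of
    the methane sub-model (None until calibration).
    """

    herbage_yield: float = 21.6
    concentrate_yield: float = 14.0
    scale: float | None = None

    def scaled(self) -> tuple[float, float]:
        s = 1.0 if self.scale is None else self.scale
        return self.herbage_yield * s, self.concentrate_yield * s


@dataclass
class SocModelParams:
    """Soil organic carbon accrual from pasture residues.

    C input = aboveground DM x herbage_c_content x root_c_fraction;
    sequestration = C input x retention_coefficient.
    """

    herbage_c_content: float = 0.45
    root_c_fraction: float = 0.25
    retention_coefficient: float | None = None

    def __post_init__(self) -> None:
        for name in ("herbage_c_content", "root_c_fraction"):
            value = getattr(self, name)
            _require(0 < value < 1, f"{name} must be in (0, 1), got {value}")
        if self.retention_coefficient is not None:
            _require(0 < self.retention_coefficient < 1,
                     "retention_coefficient must be in (0, 1)")


@dataclass
class ManureStorageParams:
    manure_ch4_yield: float = 4.0       # g CH4 per kg DM intake while housed
    slurry_m3_per_lu_day: float = 0.05


@dataclass
class ModelConstants:
    """All scalar constants of the farm-gate model, config-exposed."""

    gwp_n2o: float = 265.0
    gwp_ch4: float = 28.0
    grazing_proportion: float = 0.83
    tan_fraction_of_excreta: float = 0.65
    tan_emission_factor: float = 0.19
    frac_leach: float = 0.24
    ef_volatilization_n2o: float = 0.01
    ef_leaching_n2o: float = 0.011
    milk_n_divisor: float = 6.38
    cp_factor: float = 6.25
    meat_n_export: float = 8.0
    irrigation_volume: float = 4200.0
    pasture_utilization_fraction: float = 1.0
    milk_grazing_adjustment: bool = False
    n2o_intercept: float = 1.99
    n2o_scale: float = 1.39
    n2o_rate: float = 0.00488
    n2o_output_species: str = "n2o"
    intake_model: IntakeCoefficients = field(default_factory=IntakeCoefficients)
    excretion_model: ExcretionCoefficients = field(default_factory=ExcretionCoefficients)
    methane_model: MethaneCoefficients = field(default_factory=MethaneCoefficients)
    soc_model: SocModelParams = field(default_factory=SocModelParams)
    manure_storage: ManureStorageParams = field(default_factory=ManureStorageParams)
    supplement_emission_factor: float = 0.40
    renovation_interval_years: int = 3
    seed_rate_kg_ha: float = 25.0
    mulching_passes_per_year: int = 1
    dressings_per_year: int = 12

    def __post_init__(self) -> None:
        fractions = (
            "grazing_proportion", "tan_fraction_of_excreta", "tan_emission_factor",
            "frac_leach", "ef_volatilization_n2o", "ef_leaching_n2o",
            "pasture_utilization_fraction",
        )
        for name in fractions:
            value = getattr(self, name)
            _require(0.0 <= value <= 1.0, f"{name} must be in [0, 1], got {value}")
        for name in ("gwp_n2o", "gwp_ch4", "milk_n_divisor", "cp_factor"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.meat_n_export >= 0 and self.irrigation_volume >= 0,
                 "export and irrigation terms must be nonnegative")
        _require(self.n2o_output_species in ("n2o", "n2o_n"),
                 "n2o_output_species must be 'n2o' or 'n2o_n'")


_NESTED = {
    "intake_model": IntakeCoefficients,
    "excretion_model": ExcretionCoefficients,
    "methane_model": MethaneCoefficients,
    "soc_model": SocModelParams,
    "manure_storage": ManureStorageParams,
}


def constants_from_dict(raw: Mapping) -> ModelConstants:
    """Build :class:`ModelConstants` from a (YAML-derived) mapping.

    Unknown keys raise, so typos in a constants-override file fail loudly.
    """
    raw = dict(raw)
    raw.pop("herd", None)
    known = {f.name for f in fields(ModelConstants)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown constant name(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _NESTED and isinstance(value, Mapping):
            cleaned = {k: v for k, v in value.items() if v is not None}
            kwargs[key] = _NESTED[key](**cleaned)
        else:
            kwargs[key] = value
    return ModelConstants(**kwargs)


@dataclass
class EmissionFactorTable:
    """Activity -> (emission factor, unit basis) lookup for external resources."""

    factors: dict[str, tuple[float, str]]
    renovation_interval_years: int = 3

    def __post_init__(self) -> None:
        for name, (value, _unit) in self.factors.items():
            _require(value > 0, f"emission factor for {name!r} must be positive")

    def factor(self, activity: str) -> float:
        try:
            return self.factors[activity][0]
        except KeyError:
            raise KeyError(
                f"no emission factor for activity {activity!r}; known: "
                f"{sorted(self.factors)}"
            ) from None

    def unit(self, activity: str) -> str:
        return self.factors[activity][1]


@dataclass
class TreatmentScenario:
    """One fertilization treatment's complete driving data."""

    treatment_id: str
    n_fertilizer_rate: float            # kg N/ha/yr
    years: list[HerbageYearRecord]
    herd: HerdParameters
    constants: ModelConstants
    emission_factors: EmissionFactorTable
    dressings_per_year: int = 12

    def __post_init__(self) -> None:
        _require(self.n_fertilizer_rate >= 0, "n_fertilizer_rate must be >= 0")
        _require(len(self.years) >= 1, f"{self.treatment_id}: no yearly records")
        indices = sorted(r.year_index for r in self.years)
        _require(
            indices == list(range(1, len(self.years) + 1)),
            f"{self.treatment_id}: expected exactly one record per year index "
            f"1..{len(self.years)}, got indices {indices}",
        )

    @property
    def dressing_rate(self) -> float:
        """Fertilizer N applied per dressing, kg N/ha."""
        return self.n_fertilizer_rate / self.dressings_per_year

    def to_dict(self) -> dict:
        return {
            "treatment_id": self.treatment_id,
            "n_fertilizer_rate": self.n_fertilizer_rate,
            "dressings_per_year": self.dressings_per_year,
            "years": [asdict(r) for r in sorted(self.years, key=lambda r: r.year_index)],
            "herd": asdict(self.herd),
            "constants": asdict(self.constants),
            "emission_factors": {
                "factors": {k: list(v) for k, v in self.emission_factors.factors.items()},
                "renovation_interval_years": self.emission_factors.renovation_interval_years,
            },
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "TreatmentScenario":
        ef_raw = raw["emission_factors"]
        return cls(
            treatment_id=raw["treatment_id"],
            n_fertilizer_rate=raw["n_fertilizer_rate"],
            dressings_per_year=raw.get("dressings_per_year", 12),
            years=[HerbageYearRecord(**r) for r in raw["years"]],
            herd=HerdParameters(**raw["herd"]),
            constants=constants_from_dict(raw["constants"]),
            emission_factors=EmissionFactorTable(
                factors={k: tuple(v) for k, v in ef_raw["factors"].items()},
                renovation_interval_years=ef_raw["renovation_interval_years"],
            ),
        )


def average_over_years(records: Iterable[HerbageYearRecord], field_name: str) -> float:
    """Arithmetic mean of one yield field over a treatment's years.

    ``field_name`` must be one of ``dm_yield``, ``n_yield`` or
    ``energy_yield``; the result is in that field's units.
    """
    records = list(records)
    if not records:
        raise ValueError("average_over_years: empty record list")
    if field_name not in YIELD_FIELDS:
        raise ValueError(
            f"unknown field {field_name!r}; expected one of {YIELD_FIELDS}"
        )
    return sum(getattr(r, field_name) for r in records) / len(records)


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str, data_dir: str | Path | None = None) -> Path:
    if data_dir is not None:
        return Path(data_dir) / name
    return Path(str(resources.files("pasturecf").joinpath("data", name)))


def load_constants(path: str | Path | None = None,
                   overrides: Mapping | None = None) -> tuple[ModelConstants, HerdParameters]:
    """Read the constants file; returns (constants, herd parameters).

    ``overrides`` is a shallow mapping merged over the file contents before
    validation (used by the CLI's constants-override option).
    """
    source = Path(path) if path is not None else _data_path("constants.yaml")
    if not source.exists():
        raise FileNotFoundError(f"constants file not found: {source}")
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    if overrides:
        for key, value in overrides.items():
            if isinstance(value, Mapping) and isinstance(raw.get(key), dict):
                raw[key].update(value)
            else:
                raw[key] = value
    herd_raw = {k: v for k, v in raw.get("herd", {}).items() if v is not None}
    herd = HerdParameters(**herd_raw)
    constants = constants_from_dict(raw)
    return constants, herd


def load_emission_factors(path: str | Path | None = None,
                          renovation_interval_years: int = 3) -> EmissionFactorTable:
    source = Path(path) if path is not None else _data_path("emission_factors.csv")
    table = pd.read_csv(source, comment="#")
    missing = {"activity", "factor", "unit"} - set(table.columns)
    if missing:
        raise ValueError(f"emission factor table missing column(s) {sorted(missing)}")
    factors = {
        row.activity: (float(row.factor), str(row.unit)) for row in table.itertuples()
    }
    return EmissionFactorTable(factors=factors,
                               renovation_interval_years=renovation_interval_years)


def load_reference(path: str | Path | None = None) -> dict:
    """Published per-treatment results (milk, GWP, CF, balances, shares)."""
    source = Path(path) if path is not None else _data_path("reference.yaml")
    with open(source) as fh:
        return yaml.safe_load(fh)


def load_paper_fixtures(
    herbage_path: str | Path | None = None,
    constants_path: str | Path | None = None,
    emission_factors_path: str | Path | None = None,
    constants_overrides: Mapping | None = None,
) -> list[TreatmentScenario]:
    """Load the five packaged treatment scenarios (N0 ... N80).

    Every cell of the packaged herbage table is validated through the type
    invariants; a missing treatment-year raises a :class:`ValueError`
    naming the gap.
    """
    constants, herd = load_constants(constants_path, overrides=constants_overrides)
    ef = load_emission_factors(
        emission_factors_path,
        renovation_interval_years=constants.renovation_interval_years,
    )
    source = (Path(herbage_path) if herbage_path is not None
              else _data_path("herbage_yields.csv"))
    if not source.exists():
        raise FileNotFoundError(f"herbage fixture not found: {source}")
    table = pd.read_csv(source, comment="#")

    reference = load_reference()
    rates = reference["fertilizer_rates"]

    scenarios: list[TreatmentScenario] = []
    for treatment_id, rate in rates.items():
        rows = table[table["treatment"] == treatment_id]
        if rows.empty:
            raise ValueError(f"herbage fixture has no rows for {treatment_id}")
        years = [
            HerbageYearRecord(
                treatment_id=treatment_id,
                year_index=int(row.year),
                dm_yield=float(row.dm_yield_t_ha),
                n_yield=float(row.n_yield_kg_ha),
                energy_yield=float(row.energy_yield_gj_ha),
                sem_dm=float(row.sem_dm),
                sem_n=float(row.sem_n),
                sem_energy=float(row.sem_energy),
            )
            for row in rows.itertuples()
        ]
        expected = set(range(1, 4))
        found = {r.year_index for r in years}
        if found != expected:
            raise ValueError(
                f"{treatment_id}: missing year record(s) {sorted(expected - found)}"
            )
        scenarios.append(
            TreatmentScenario(
                treatment_id=treatment_id,
                n_fertilizer_rate=float(rate),
                years=years,
                herd=herd,
                constants=constants,
                emission_factors=ef,
                dressings_per_year=constants.dressings_per_year,
            )
        )
    return scenarios
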