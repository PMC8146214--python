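"""GHG inventory line items and GWP aggregation."""

import math

import numpy as np
import pytest

from pasturecf.forage_energy import estimate_dm_intake
from pasturecf.ghg_inventory import (
    GhgInventory,
    aggregate_gwp,
    embodied_inputs,
    enteric_ch4,
    irrigation_emissions,
    management_emissions,
    manure_storage_emissions,
    n2o_direct,
    n2o_indirect,
    soc_change,
)
from pasturecf.scenario_model import (
    ManureStorageParams,
    MethaneCoefficients,
    SocModelParams,
    load_emission_factors,
)


@pytest.fixture(scope="module")
def ef():
    return load_emission_factors()


class TestN2oDirect:
    @pytest.mark.parametrize("balance,expected", [
        (0.0, 3.38),       # exp(0): intercept + scale
        (86.0, 4.105),     # moderate surplus
        (706.0, 45.57),    # extreme surplus
        (-119.0, 2.769),   # soil-N mining still emits the background
    ])
    def test_hand_evaluations(self, balance, expected):
        assert n2o_direct(balance) == pytest.approx(expected, abs=0.005)

    def test_matches_independent_evaluation_on_grid(self):
        x = np.linspace(-500.0, 1000.0, 10_000)
        expected = 1.99 + 1.39 * np.exp(0.00488 * x)
        computed = np.array([n2o_direct(v) for v in x])
        assert np.allclose(computed, expected, atol=1e-9)

    def test_strictly_increasing_and_convex(self):
        x = np.linspace(-500.0, 1000.0, 10_000)
        y = np.array([n2o_direct(v) for v in x])
        assert np.all(np.diff(y) > 0)
        assert np.all(np.diff(y, 2) > 0)

    def test_bounded_below_by_intercept(self):
        assert n2o_direct(-1e6) >= 1.99
        assert n2o_direct(-500.0) > 1.99

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            n2o_direct(float("nan"))


class TestN2oIndirect:
    def test_zero_inputs(self):
        assert n2o_indirect(0.0, 0.0, 0.01, 0.011) == 0.0

    def test_volatilization_path(self):
        assert n2o_indirect(100.0, 0.0, 0.01, 0.011) == pytest.approx(1.571, abs=0.001)

    def test_leaching_path(self):
        assert n2o_indirect(0.0, 100.0, 0.01, 0.011) == pytest.approx(1.729, abs=0.001)

    def test_ef_bounds(self):
        with pytest.raises(ValueError):
            n2o_indirect(10.0, 10.0, 0.5, 0.011)


class TestEntericCh4:
    def _intake(self):
        return estimate_dm_intake(8.6, 380.0, 3.2)

    def test_per_cow_annual_in_band(self):
        coeffs = MethaneCoefficients(scale=0.8)
        per_ha = enteric_ch4(self._intake(), 1.0, coeffs)  # stocking 1 -> per cow
        assert 60.0 <= per_ha <= 160.0

    def test_zero_intake_gives_zero(self):
        from pasturecf.forage_energy import IntakeProfile
        empty = IntakeProfile(0.0, 0.0, 0.0, 0.0, 0.0)
        assert enteric_ch4(empty, 4.7) == 0.0

    def test_out_of_band_flagged(self):
        coeffs = MethaneCoefficients(herbage_yield=60.0, concentrate_yield=60.0,
                                     scale=1.0)
        with pytest.warns(UserWarning, match="CH4"):
            enteric_ch4(self._intake(), 4.7, coeffs)

    def test_calibrated_control_share(self, results_by_id):
        # the methane-yield scale is solved on the control treatment
        assert results_by_id["N0"].footprint.shares["enteric_ch4"] == pytest.approx(
            65.0, abs=1e-6)


class TestEmbodiedInputs:
    def test_fertilizer_term(self, ef):
        items = embodied_inputs(880.0, ef)
        assert items["fertilizer_embodied"] == pytest.approx(880 * 8.60)

    def test_zero_rate_keeps_operations(self, ef):
        items = embodied_inputs(0.0, ef)
        assert items["fertilizer_embodied"] == 0.0
        assert items["seeds_and_renovation"] > 0
        # no dressings applied, but mulching remains
        assert items["field_operations"] == pytest.approx(21.24)

    def test_seed_term_per_renovation(self, ef):
        items = embodied_inputs(0.0, ef, renovation_interval=1, seed_rate=25.0)
        # one full renovation charged this year includes 25 kg seed x 2.03
        assert items["seeds_and_renovation"] == pytest.approx(
            75.42 + 22.76 + 50.75)

    def test_missing_factor_raises(self):
        from pasturecf.scenario_model import EmissionFactorTable
        sparse = EmissionFactorTable(factors={"tillage": (75.42, "kg/ha")})
        with pytest.raises(KeyError):
            embodied_inputs(100.0, sparse)


class TestIrrigationAndManagement:
    def test_irrigation_product(self, ef):
        assert irrigation_emissions(4200.0, ef) == pytest.approx(1806.0)

    def test_irrigation_zero_and_linearity(self, ef):
        assert irrigation_emissions(0.0, ef) == 0.0
        assert irrigation_emissions(2100.0, ef) == pytest.approx(903.0)

    def test_milking_term(self, ef):
        # 16.6 t milk at 0.02 kg CO2eq per kg
        value = management_emissions(16.6, 0.0, ef, shed_fraction=0.17)
        assert value == pytest.approx(332.0)

    def test_zero_stock_no_shed_term(self, ef):
        assert management_emissions(0.0, 0.0, ef, 0.17) == 0.0

    def test_manure_storage_small_share(self, results):
        # year-round grazing keeps manure storage a minor item (~2-4%)
        for r in results:
            share = r.footprint.shares["manure_storage"]
            assert share < 7.0

    def test_manure_storage_components(self, ef):
        intake = estimate_dm_intake(8.6, 380.0, 3.2)
        params = ManureStorageParams(manure_ch4_yield=0.0,
                                     slurry_m3_per_lu_day=0.05)
        slurry_only = manure_storage_emissions(intake, 4.7, ef, params, 0.17)
        assert slurry_only == pytest.approx(4.7 * 0.17 * 365 * 0.05 * 0.06)


class TestSocChange:
    def _params(self, retention=0.41):
        return SocModelParams(herbage_c_content=0.45, root_c_fraction=0.25,
                              retention_coefficient=retention)

    def test_offset_is_stoichiometric(self):
        seq, offset = soc_change(20.0, self._params())
        assert offset / seq == pytest.approx(-44.0 / 12.0)

    def test_monotone_in_dm(self):
        lo, _ = soc_change(18.5, self._params())
        hi, _ = soc_change(21.5, self._params())
        assert hi > lo

    def test_linear_extrapolation_band(self, results_by_id):
        # retention calibrated on the control extrapolates to the highest
        # rate within 15% of its published sequestration (0.91 t C/ha)
        assert results_by_id["N80"].footprint.soc_sequestration == pytest.approx(
            0.91, rel=0.15)

    def test_uncalibrated_raises(self):
        with pytest.raises(ValueError, match="calibrated"):
            soc_change(20.0, SocModelParams())


class TestAggregation:
    def test_gwp_factors(self):
        gross, net = aggregate_gwp(ch4_mass=1.0, n2o_mass=1.0)
        assert gross == 293.0 and net == 293.0

    def test_empty_inventory(self):
        gross, net = aggregate_gwp()
        assert gross == 0.0 and net == 0.0

    def test_soc_offset_enters_net_only(self):
        gross, net = aggregate_gwp(co2_mass=100.0, soc_offset=-30.0)
        assert gross == 100.0 and net == 70.0

    def test_inventory_additivity(self, results):
        a, b = results[0].inventory, results[-1].inventory
        combined = a + b
        assert combined.gwp_gross == pytest.approx(a.gwp_gross + b.gwp_gross)
        assert combined.gwp_net == pytest.approx(a.gwp_net + b.gwp_net)

    def test_inventory_sign_guards(self):
        with pytest.raises(ValueError):
            GhgInventory(enteric_ch4=-1.0)
        with pytest.raises(ValueError):
            GhgInventory(soc_offset=5.0)

    def test_gwp_net_strictly_increasing_across_treatments(self, results):
        nets = [r.footprint.gwp_net for r in results]
        assert all(a < b for a, b in zip(nets, nets[1:]))


def test_contribution_share_anchors(results_by_id):
    # published contribution structure: fertilizer+seed inputs average ~12%,
    # SOC cuts the footprint by ~14% on average
    inputs = np.mean([
        r.footprint.shares["fertilizer_embodied"]
        + r.footprint.shares["seeds_and_renovation"]
        for r in results_by_id.values()
    ])
    assert inputs == pytest.approx(12.0, abs=5.0)
    reductions = [
        (1.0 - r.footprint.gwp_net / r.footprint.gwp_gross) * 100.0
        for r in results_by_id.values()
    ]
    assert np.mean(reductions) == pytest.approx(14.0, abs=5.0)
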