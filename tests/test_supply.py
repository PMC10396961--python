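import numpy as np
import pandas as pd
import pytest

from woodcarbon.growth import MonodCurve, RootShootParams, agb_at_age
from woodcarbon.products import ConversionTable, LandfillParams, ProductShares
from woodcarbon.stand import HalfLives, StandParams, harvest_event, PoolState
from woodcarbon.supply import (
    SCENARIOS,
    AllocationError,
    CountryProfile,
    WorldInputs,
    allocate_supply,
    clearcut_equivalent_area,
    run_scenario,
    scale_global,
)
from woodcarbon.valuation import DiscountSpec


class TestClearcutArea:
    @pytest.mark.parametrize("volume, y, expected", [(1000.0, 100.0, 10.0), (0.0, 5.0, 0.0)])
    def test_basic(self, volume, y, expected):
        assert clearcut_equivalent_area(volume, y) == expected

    def test_bad_inputs(self):
        with pytest.raises(AllocationError):
            clearcut_equivalent_area(10.0, 0.0)
        with pytest.raises(ValueError):
            clearcut_equivalent_area(-1.0, 10.0)

    def test_yield_consistent_with_stand_module(self, simple_curve, linear_roots):
        """Recovered volume per hectare round-trips through harvest_event."""
        table = ConversionTable()
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.25,
            product_shares=ProductShares(llp=1.0, slp=0, vslp_wfl=0, vslp_ind=0),
        )
        age, eff = 20.0, 0.7
        agb = agb_at_age(simple_curve, age)
        state = PoolState(age=age, live_agb=agb, live_bgb=linear_roots.bgb(agb))
        _, flows = harvest_event(state, params, efficiency=eff)
        vol_per_ha = sum(flows.values()) / table.carbon_per_m3
        expected = agb * (1 - 0.25) * eff / table.carbon_per_m3
        assert vol_per_ha == pytest.approx(expected, rel=1e-12)
        assert clearcut_equivalent_area(expected * 10, vol_per_ha) == pytest.approx(10.0)


class TestScaleGlobal:
    def test_definition(self):
        assert scale_global(80.0) == pytest.approx(100.0)
        assert scale_global(0.0) == 0.0

    def test_linearity(self):
        a, b = 12.3, 45.6
        assert scale_global(a + b) == pytest.approx(scale_global(a) + scale_global(b))

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            scale_global(1.0, coverage=0.0)


def _profile(name="A", plantation_area=0.0, tropical=False, **kw):
    defaults = dict(
        plantation_curve=MonodCurve(300.0, 10.0),
        secondary_curve=MonodCurve(200.0, 20.0),
        plantation_rotation=10,
        secondary_age_at_harvest=20.0,
        harvest_efficiency=1.0,
        slash_fraction_secondary=0.25,
        slash_fraction_plantation=0.2,
        net_import_share=0.0,
        export_share=0.0,
        construction_share=1.0,
        rootshoot=RootShootParams(0.25, 1.0),
    )
    defaults.update(kw)
    return CountryProfile(
        name=name, tropical=tropical, plantation_area_2010=plantation_area, **defaults
    )


class TestAllocateSupply:
    def _run(self, production_value, plantation_area, scenario=1, years=5):
        prof = _profile(plantation_area=plantation_area)
        production = pd.DataFrame(
            {"A": np.full(years, production_value)}, index=2010 + np.arange(years)
        )
        plan = allocate_supply(
            production, {"A": prof}, SCENARIOS[scenario], ConversionTable()
        )
        return plan.countries["A"]

    def test_demand_within_plantation_capacity_uses_no_secondary(self):
        cp = self._run(production_value=1e5, plantation_area=1e6)
        assert cp.sec_volume.sum() == 0.0
        assert np.allclose(cp.plant_volume, 1e5)
        assert np.allclose(cp.supplied, cp.production)

    def test_secondary_area_linear_in_residual_demand(self):
        base = self._run(1e5, plantation_area=0.0)
        double = self._run(2e5, plantation_area=0.0)
        assert np.allclose(double.sec_area_mid, 2 * base.sec_area_mid)

    def test_plantation_slots_counted_once(self):
        """Re-harvest of a rotated hectare adds no new plantation area."""
        cp = self._run(1e5, plantation_area=1e9, years=25)  # rotation 10
        assert cp.plant_new_area[:10].sum() == pytest.approx(cp.plant_new_area.sum())
        assert np.allclose(cp.plant_new_area[10:], 0.0)

    def test_mature_mix_splits_area(self):
        cp = self._run(1e5, plantation_area=0.0, scenario=3)
        assert np.allclose(cp.sec_area_mature, cp.sec_area_mid)
        assert cp.sec_volume.sum() == pytest.approx(5e5)

    def test_conversion_scenario_reduces_later_secondary_harvest(self):
        base = self._run(1e5, plantation_area=0.0, years=25)
        conv = self._run(1e5, plantation_area=0.0, scenario=2, years=25)
        assert conv.sec_volume[:10].sum() == pytest.approx(base.sec_volume[:10].sum())
        assert conv.sec_volume[10:].sum() < base.sec_volume[10:].sum()
        assert np.allclose(conv.supplied, conv.production, rtol=1e-12)


class TestScenarioOrdering:
    def test_reduced_wood_fuel_costs_no_more_than_baseline(self, small_world):
        r1 = run_scenario(1, small_world)
        r7 = run_scenario(7, small_world)
        assert r7.annualized_cost <= r1.annualized_cost
        assert r7.area_total_mha <= r1.area_total_mha

    def test_productive_plantations_need_less_secondary_forest(self, small_world):
        r1 = run_scenario(1, small_world)
        r5 = run_scenario(5, small_world)
        assert r5.area_secondary_mha <= r1.area_secondary_mha

    def test_all_scenarios_run_and_balance(self, small_world):
        for sid in range(1, 8):
            r = run_scenario(sid, small_world)
            assert np.isfinite(r.annualized_cost)
            assert r.substitution_savings >= 0
            for cp in r.plan.countries.values():
                assert np.allclose(cp.supplied, cp.production, rtol=1e-9)


# ---------------------------------------------------------------------------
# two-country micro-world: totals hand-computed by an independent
# spreadsheet-style year-by-year calculation


def _sheet_pdv(a_max, k_half, age0, rs, slash, eff, s_llp, s_slp, s_wfl,
               hl, lf, d, n_years):
    """Plain year-loop bookkeeping, kept deliberately flat and explicit."""
    agb = lambda t: a_max * t / (k_half + t)
    r = lambda h: 2.0 ** (-1.0 / h)
    felled_ag, felled_bg = agb(age0), rs * agb(age0)
    base = felled_ag + felled_bg

    slash_p = felled_ag * slash + felled_ag * (1 - slash) * (1 - eff)
    recovered = felled_ag * (1 - slash) * eff
    llp, slp = recovered * s_llp, recovered * s_slp
    roots = felled_bg
    landfill = 0.0
    emitted0 = recovered * s_wfl

    stored_h = [slash_p + roots + llp + slp]          # end of year 0
    stored_cf = [agb(age0 + 1) + rs * agb(age0 + 1)]
    ch4 = [0.0]
    for t in range(1, n_years + 1):
        landfill_old = landfill * r(hl["landfill"])
        ch4.append((landfill - landfill_old) * lf["methane_fraction"])
        llp_new = llp * r(hl["llp"])
        landfill = landfill_old + (llp - llp_new) * lf["landfill_fraction"]
        llp = llp_new
        slash_p *= r(hl["slash"])
        roots *= r(hl["roots"])
        slp *= r(hl["slp"])
        regrow = agb(t) + rs * agb(t)
        stored_h.append(slash_p + roots + llp + slp + landfill + regrow)
        stored_cf.append(agb(age0 + 1 + t) + rs * agb(age0 + 1 + t))

    gap = [cf - base - (h - base) for cf, h in zip(stored_cf, stored_h)]
    deltas = [gap[0]] + [gap[t] - gap[t - 1] for t in range(1, n_years + 1)]
    pdv_tc = sum(dc / (1 + d) ** t for t, dc in enumerate(deltas))
    extra = (16.0 / 12.0) * lf["gwp"] - 44.0 / 12.0
    pdv_co2e = sum(
        (dc * 44.0 / 12.0 + m * extra) / (1 + d) ** t
        for t, (dc, m) in enumerate(zip(deltas, ch4))
    )
    return pdv_tc, pdv_co2e


def test_two_country_toy_world_matches_hand_calculation():
    """End-to-end pipeline total equals an independent spreadsheet total."""
    table = ConversionTable(
        ratios={"llp": 1.0, "slp": 1.0, "vslp_wfl": 1.0, "vslp_ind": 1.0}
    )
    hl = HalfLives()
    lf = LandfillParams()
    profiles = {
        "A": _profile("A", secondary_curve=MonodCurve(200.0, 20.0),
                      secondary_age_at_harvest=20.0, slash_fraction_secondary=0.25),
        "B": _profile("B", secondary_curve=MonodCurve(150.0, 30.0),
                      secondary_age_at_harvest=30.0, slash_fraction_secondary=0.2),
    }
    demand = pd.DataFrame(
        {
            "llp": {"A": 31250.0, "B": 0.0},
            "slp": {"A": 0.0, "B": 0.0},
            "vslp_wfl": {"A": 0.0, "B": 25000.0},
            "vslp_ind": {"A": 0.0, "B": 0.0},
        }
    )
    inputs = WorldInputs(
        profiles=profiles, demand_2010=demand, demand_2050=demand.copy(),
        conversion=table, half_lives=hl, methane=lf,
        discount=DiscountSpec(0.04, 40), coverage=1.0,
    )
    result = run_scenario(1, inputs)

    # --- independent totals -------------------------------------------------
    hl_d = dict(slash=hl.slash, roots=hl.roots, llp=hl.llp, slp=hl.slp,
                landfill=hl.landfill)
    lf_d = dict(landfill_fraction=lf.landfill_fraction_of_llp_decay,
                methane_fraction=lf.methane_fraction, gwp=lf.gwp100_ch4)
    # country A: 31250 m3/yr of long-lived wood; yield 100*(0.75)/0.24
    area_a = 31250.0 / (100.0 * 0.75 / 0.24)          # 100 ha/yr
    pdv_a_tc, pdv_a_co2e = _sheet_pdv(200.0, 20.0, 20.0, 0.25, 0.25, 1.0,
                                      1.0, 0.0, 0.0, hl_d, lf_d, 0.04, 40)
    # country B: 25000 m3/yr of fuelwood; yield 75*(0.8)/0.24
    area_b = 25000.0 / (75.0 * 0.8 / 0.24)            # 100 ha/yr
    pdv_b_tc, pdv_b_co2e = _sheet_pdv(150.0, 30.0, 30.0, 0.25, 0.2, 1.0,
                                      0.0, 0.0, 1.0, hl_d, lf_d, 0.04, 40)
    k = 40
    expected_tc = k * (area_a * pdv_a_tc + area_b * pdv_b_tc)
    expected_co2e = k * (area_a * pdv_a_co2e + area_b * pdv_b_co2e)

    assert result.pdv_total_tc == pytest.approx(expected_tc, rel=1e-6)
    assert result.pdv_total_co2e == pytest.approx(expected_co2e, rel=1e-6)
    assert result.annualized_cost == pytest.approx(expected_co2e / k / 1e9, rel=1e-6)
    # flat demand: all cost is at 2010 level
    assert result.additional_cost == pytest.approx(0.0, abs=1e-12)
    # substitution: construction LLP at 1.2, fuelwood at 0.175 (tC saved)
    subst_tc = k * (31250.0 * 0.24 * 1.2 + 25000.0 * 0.24 * 0.175)
    assert result.substitution_savings == pytest.approx(
        subst_tc * 44 / 12 / k / 1e9, rel=1e-9
    )
    assert result.area_secondary_mha == pytest.approx(k * (area_a + area_b) / 1e6, rel=1e-9)
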