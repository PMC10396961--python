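import math

import numpy as np
import pytest

from conftest import random_stand_params
from woodcarbon.growth import MonodCurve, RootShootParams, agb_at_age
from woodcarbon.products import LandfillParams, ProductShares
from woodcarbon.stand import (
    HalfLives,
    PoolState,
    StandParams,
    annual_atmosphere_delta,
    decay_step,
    harvest_event,
    simulate_stand,
)


class TestDecayStep:
    @pytest.mark.parametrize(
        "stock, half_life, expected_remaining",
        [
            (100.0, 1.0, 50.0),
            (0.0, 7.0, 0.0),
            (100.0, 10.0, 100.0 * 2.0 ** -0.1),  # 93.303...
        ],
    )
    def test_closed_form(self, stock, half_life, expected_remaining):
        remaining, released = decay_step(stock, half_life)
        assert remaining == pytest.approx(expected_remaining, rel=1e-12)
        assert remaining + released == stock  # exact conservation

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decay_step(-1.0, 5.0)
        with pytest.raises(ValueError):
            decay_step(10.0, 0.0)

    def test_infinite_half_life_is_inert(self):
        assert decay_step(42.0, math.inf) == (42.0, 0.0)

    @pytest.mark.parametrize("half_life", [1.0, 2.5, 7.0, 29.0, 100.0])
    def test_halves_after_one_half_life(self, half_life):
        """Annual steps compound to 2^(-t/h): integer half-lives halve exactly."""
        stock = 64.0
        n = int(round(half_life * 4))
        for _ in range(n):
            stock, _ = decay_step(stock, half_life)
        assert stock == pytest.approx(64.0 * 2.0 ** (-n / half_life), rel=1e-12)


def _state(agb, bgb):
    return PoolState(age=20.0, live_agb=agb, live_bgb=bgb)


class TestHarvestEvent:
    def test_all_vslp_partition(self, simple_curve, linear_roots):
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.3,
            product_shares=ProductShares(llp=0, slp=0, vslp_wfl=1.0, vslp_ind=0),
        )
        new, flows = harvest_event(_state(100.0, 25.0), params, efficiency=1.0)
        assert new.slash == pytest.approx(30.0)
        assert new.dead_roots == pytest.approx(25.0)
        assert new.cumulative_emitted == pytest.approx(70.0)  # burned at once
        assert new.live_agb == new.live_bgb == 0.0 and new.age == 0.0
        assert flows["vslp_wfl"] == pytest.approx(70.0)

    def test_llp_slp_split(self, simple_curve, linear_roots):
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.3,
            product_shares=ProductShares(llp=0.5, slp=0.5, vslp_wfl=0, vslp_ind=0),
        )
        new, flows = harvest_event(_state(100.0, 25.0), params, efficiency=1.0)
        assert new.llp_stock == pytest.approx(35.0)
        assert new.slp_stock == pytest.approx(35.0)
        assert new.cumulative_emitted == pytest.approx(0.0)

    def test_bare_stand_only_resets_age(self, basic_params):
        state = PoolState(age=20.0, slash=3.0)
        new, flows = harvest_event(state, basic_params, efficiency=0.8)
        assert new.age == 0.0
        assert new.slash == 3.0
        assert all(v == 0.0 for v in flows.values())

    def test_unrecovered_wood_stays_as_slash(self, simple_curve, linear_roots):
        """Harvest losses (1 - efficiency) remain on site, conserving carbon."""
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.2,
            product_shares=ProductShares(llp=1.0, slp=0, vslp_wfl=0, vslp_ind=0),
        )
        new, flows = harvest_event(_state(100.0, 25.0), params, efficiency=0.6)
        assert flows["llp"] == pytest.approx(80.0 * 0.6)
        assert new.slash == pytest.approx(20.0 + 80.0 * 0.4)
        total = new.slash + new.dead_roots + new.llp_stock + new.cumulative_emitted
        assert total == pytest.approx(125.0, abs=1e-12)

    def test_bad_efficiency_rejected(self, basic_params):
        with pytest.raises(ValueError):
            harvest_event(_state(10, 2), basic_params, efficiency=0.0)


class TestSimulateStand:
    def test_no_harvest_means_zero_deltas(self, basic_params):
        traj = simulate_stand(basic_params, 50, 30.0, harvest=False)
        assert np.allclose(traj.delta_series, 0.0, atol=1e-12)

    def test_year_zero_delta_is_vslp_plus_foregone_growth(self, simple_curve, linear_roots):
        """First-year cost = burned wood + counterfactual increment foregone."""
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.3,
            product_shares=ProductShares(llp=0, slp=0, vslp_wfl=1.0, vslp_ind=0),
        )
        traj = simulate_stand(params, 2, 20.0, efficiency=1.0)
        cf_inc = (agb_at_age(simple_curve, 21) - 100.0) * 1.25  # agb + linear roots
        assert traj.delta_series[0] == pytest.approx(70.0 + cf_inc, rel=1e-12)

    def test_deltas_telescope_to_storage_gap(self, basic_params):
        traj = simulate_stand(basic_params, 80, 40.0, efficiency=0.7)
        assert traj.delta_series.sum() == pytest.approx(traj.storage_gap[-1], abs=1e-9)
        assert np.allclose(annual_atmosphere_delta(traj), traj.delta_series, atol=1e-12)

    def test_nothing_leaves_site_when_pools_are_inert(self, simple_curve, linear_roots):
        """slash_fraction 1 plus infinite half-lives keep all carbon on site."""
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=1.0,
            product_shares=ProductShares(llp=1.0, slp=0, vslp_wfl=0, vslp_ind=0),
            half_lives=HalfLives(math.inf, math.inf, math.inf, math.inf, math.inf),
        )
        traj = simulate_stand(params, 60, 20.0, efficiency=0.9)
        assert traj.harvest_path[-1].cumulative_emitted == 0.0
        # all felled carbon stays in dead pools, so the storage gap is the
        # counterfactual's extra growth minus the regrown live biomass
        live_cf = traj.counterfactual_path[-1].live_agb + traj.counterfactual_path[-1].live_bgb
        live_h = traj.harvest_path[-1].live_agb + traj.harvest_path[-1].live_bgb
        expected = (live_cf - traj.cf_base_storage) - live_h
        assert traj.storage_gap[-1] == pytest.approx(expected, abs=1e-9)

    def test_regrowth_turns_deltas_negative_late_in_cycle(self, basic_params):
        """Fast regrowth vs an old counterfactual yields net removals."""
        traj = simulate_stand(basic_params, 41, 60.0, efficiency=0.7)
        assert traj.delta_series[0] > 0
        assert traj.delta_series[25:].max() < 0

    def test_carbon_closure_each_year(self, basic_params):
        traj = simulate_stand(basic_params, 100, 40.0, efficiency=0.7)
        states = traj.harvest_path
        prev_total = traj.harvest_base_storage
        for t, s in enumerate(states):
            prev_emitted = states[t - 1].cumulative_emitted if t else 0.0
            change = (s.total_stored + s.cumulative_emitted) - (prev_total + prev_emitted)
            assert change == pytest.approx(traj.growth_series[t], abs=1e-9), f"year {t}"
            prev_total = s.total_stored

    def test_closure_holds_for_random_parameters(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params, eff, age = random_stand_params(rng)
            traj = simulate_stand(params, 120, age, efficiency=eff)
            totals = np.array(
                [s.total_stored + s.cumulative_emitted for s in traj.harvest_path]
            )
            expected = traj.harvest_base_storage + np.cumsum(traj.growth_series)
            assert np.allclose(totals, expected, atol=1e-9)

    def test_thinning_moves_carbon_without_breaking_closure(self, simple_curve, linear_roots):
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.3,
            product_shares=ProductShares(llp=1.0, slp=0, vslp_wfl=0, vslp_ind=0),
            thinning_schedule=((10, 0.3),),
            rotation=20,
        )
        traj = simulate_stand(params, 60, 40.0, efficiency=0.8)
        totals = np.array(
            [s.total_stored + s.cumulative_emitted for s in traj.harvest_path]
        )
        expected = traj.harvest_base_storage + np.cumsum(traj.growth_series)
        assert np.allclose(totals, expected, atol=1e-9)
        # thinned wood reached the product pool between harvests
        llp = np.array([s.llp_stock for s in traj.harvest_path])
        assert llp[11] > llp[9] * 2 ** (-2 / 35.0) + 1e-6

    def test_delayed_first_harvest_grows_first(self, simple_curve, linear_roots):
        """A stand planted at age 0 and cut at its rotation age sequesters first."""
        params = StandParams(
            curve=simple_curve, rootshoot=linear_roots, slash_fraction=0.3,
            product_shares=ProductShares(llp=1.0, slp=0, vslp_wfl=0, vslp_ind=0),
            rotation=10,
        )
        slow_cf = MonodCurve(a_max=100.0, k_half=40.0)
        traj = simulate_stand(
            params, 41, 10.0, efficiency=0.8,
            first_harvest_year=10, cf_curve=slow_cf, cf_start_age=0.0,
        )
        # before the first cut the fast stand outgrows the counterfactual
        assert np.all(traj.delta_series[:10] < 0)
        assert traj.delta_series[10] > 0
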