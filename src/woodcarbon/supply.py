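"""Scenario engine: allocate wood demand to forests and price the carbon.

For each producing country, projected roundwood demand is met first from
the plantation estate existing in 2010 (a rotating pool of hectares:
capacity = estate area / rotation x rotation-age yield) and the
remainder from clear-cut-equivalent harvests of middle-aged secondary
forest.  Seven supply scenarios modify this allocation:

1. baseline — secondary forests regrow after harvest;
2. harvested secondary stands are converted to plantations that supply
   wood again every plantation rotation;
3. half of secondary harvest area comes from mature stands (40 years
   older than middle-aged);
4. 2 Mha yr^-1 of tropical agricultural land is converted to new
   plantations (counterfactual: secondary regrowth on that land);
5. existing plantations are 25 % more productive;
6. tropical secondary harvests reach a high-efficiency benchmark;
7. fuelwood demand declines linearly to 50 % of its 2050 baseline.

Carbon costs follow the per-hectare pool bookkeeping (`woodcarbon.stand`)
valued as harvest-year equivalents (`woodcarbon.valuation`), multiplied
by newly harvested areas and summed over harvest years and forest types.
Because per-country inputs cover only the ~30 countries producing 80 %
of the world's wood, totals are divided by that coverage to give global
estimates.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

from .growth import MonodCurve, RootShootParams, agb_at_age
from .products import (
    PRODUCTS,
    CO2_PER_C,
    ConversionTable,
    LandfillParams,
    ProductShares,
    roundwood_from_consumption,
)
from .stand import HalfLives, StandParams, delta_co2e_series, simulate_stand
from .valuation import DiscountSpec, SubstitutionFactors, pdv
from .demand import apply_trade, interpolate_demand

__all__ = [
    "CountryProfile",
    "ScenarioConfig",
    "SCENARIOS",
    "WorldInputs",
    "CountryPlan",
    "HarvestPlan",
    "ScenarioResult",
    "AllocationError",
    "allocate_supply",
    "clearcut_equivalent_area",
    "scale_global",
    "run_scenario",
]


class AllocationError(RuntimeError):
    """Demand cannot be met under the configured yields."""


@dataclass(frozen=True)
class CountryProfile:
    """Per-country supply parameters."""

    name: str
    tropical: bool
    plantation_area_2010: float            # ha
    plantation_curve: MonodCurve
    secondary_curve: MonodCurve
    plantation_rotation: int               # yr
    secondary_age_at_harvest: float        # yr, middle-aged stands
    harvest_efficiency: float              # recovered share of removable wood
    slash_fraction_secondary: float
    slash_fraction_plantation: float
    net_import_share: float                # base-year net imports / consumption
    export_share: float                    # base-year share of global exports
    construction_share: float              # LLP share used in construction
    rootshoot: RootShootParams = field(default_factory=RootShootParams)

    def __post_init__(self) -> None:
        if self.plantation_area_2010 < 0:
            raise ValueError(f"{self.name}: plantation area must be >= 0")
        if not 0.0 < self.harvest_efficiency <= 1.0:
            raise ValueError(
                f"{self.name}: harvest_efficiency={self.harvest_efficiency} "
                "outside (0, 1]"
            )
        if self.plantation_rotation <= 0:
            raise ValueError(f"{self.name}: plantation_rotation must be positive")
        if self.secondary_age_at_harvest <= 0:
            raise ValueError(f"{self.name}: secondary_age_at_harvest must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Flags describing one of the seven supply scenarios."""

    id: int
    name: str
    regrow_secondary_as: str = "secondary"        # or "plantation" (scenario 2)
    mature_fraction: float = 0.0                  # scenario 3
    new_tropical_plantations_ha_yr: float = 0.0   # scenario 4, global
    plantation_productivity_multiplier: float = 1.0  # scenario 5
    tropical_efficiency_boost: bool = False       # scenario 6
    wood_fuel_multiplier_2050: float = 1.0        # scenario 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.mature_fraction <= 1.0:
            raise ValueError(f"mature_fraction={self.mature_fraction} outside [0, 1]")
        if self.regrow_secondary_as not in ("secondary", "plantation"):
            raise ValueError(f"unknown regrow_secondary_as {self.regrow_secondary_as!r}")
        if not 0.0 < self.wood_fuel_multiplier_2050 <= 1.0:
            raise ValueError("wood_fuel_multiplier_2050 must be in (0, 1]")


SCENARIOS: dict[int, ScenarioConfig] = {
    1: ScenarioConfig(1, "secondary harvest and regrowth"),
    2: ScenarioConfig(2, "secondary harvest and conversion", regrow_secondary_as="plantation"),
    3: ScenarioConfig(3, "secondary mixed harvest", mature_fraction=0.5),
    4: ScenarioConfig(4, "new tropical plantations", new_tropical_plantations_ha_yr=2e6),
    5: ScenarioConfig(5, "high plantation productivity", plantation_productivity_multiplier=1.25),
    6: ScenarioConfig(6, "higher harvest efficiency", tropical_efficiency_boost=True),
    7: ScenarioConfig(7, "reduced wood fuel demand", wood_fuel_multiplier_2050=0.5),
}


@dataclass
class WorldInputs:
    """Everything a scenario run needs besides the scenario itself."""

    profiles: dict[str, CountryProfile]
    demand_2010: pd.DataFrame          # index country, columns product, m3 RWE
    demand_2050: pd.DataFrame
    conversion: ConversionTable = field(default_factory=ConversionTable)
    half_lives: HalfLives = field(default_factory=HalfLives)
    methane: LandfillParams = field(default_factory=LandfillParams)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    substitution: SubstitutionFactors = field(default_factory=SubstitutionFactors)
    start_year: int = 2010
    end_year: int = 2050
    n_harvest_years: int = 40
    coverage: float = 0.8              # share of world production covered
    high_efficiency: float = 0.8       # scenario 6 benchmark

    def __post_init__(self) -> None:
        for df_name in ("demand_2010", "demand_2050"):
            df = getattr(self, df_name)
            missing = set(PRODUCTS) - set(df.columns)
            if missing:
                raise ValueError(f"{df_name} missing product columns {sorted(missing)}")
            unknown = set(df.index) - set(self.profiles)
            if unknown:
                raise ValueError(f"{df_name} has countries without profiles: {sorted(unknown)}")


def clearcut_equivalent_area(volume: float, yield_per_ha: float) -> float:
    """Hectares that must be clear-cut to produce ``volume`` m3."""
    if yield_per_ha <= 0:
        raise AllocationError(f"non-positive yield {yield_per_ha} m3/ha")
    if volume < 0:
        raise ValueError(f"volume must be non-negative, got {volume}")
    return volume / yield_per_ha


def scale_global(total_covered: float, coverage: float = 0.8) -> float:
    """Scale a quantity from the covered producer set to the globe.

    Inputs cover the countries producing ``coverage`` (default 80 %) of
    the world's wood; dividing by that share gives the global estimate.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    return total_covered / coverage


def _stand_yield(
    curve: MonodCurve, age: float, slash_fraction: float, efficiency: float,
    conversion: ConversionTable,
) -> float:
    """Recovered wood volume (m3/ha) from clear-cutting a stand of ``age``."""
    carbon = agb_at_age(curve, age) * (1.0 - slash_fraction) * efficiency
    return carbon / conversion.carbon_per_m3


def _scaled_plantation_curve(profile: CountryProfile, scenario: ScenarioConfig) -> MonodCurve:
    m = scenario.plantation_productivity_multiplier
    c = profile.plantation_curve
    return c if m == 1.0 else MonodCurve(a_max=c.a_max * m, k_half=c.k_half)


def _secondary_efficiency(
    profile: CountryProfile, scenario: ScenarioConfig, high_efficiency: float
) -> float:
    if scenario.tropical_efficiency_boost and profile.tropical:
        return max(profile.harvest_efficiency, high_efficiency)
    return profile.harvest_efficiency


@dataclass
class CountryPlan:
    """Year-by-year harvest plan for one country (arrays over K years)."""

    country: str
    years: np.ndarray
    production: np.ndarray            # m3 required per year
    plant_volume: np.ndarray
    plant_area_harvested: np.ndarray  # ha cut per year (slots, incl. re-use)
    plant_new_area: np.ndarray        # ha counted as new (first use of a slot)
    newplant_volume: np.ndarray       # scenario 4 cohorts
    newplant_new_area: np.ndarray
    converted_volume: np.ndarray      # scenario 2 cohorts re-supplying
    sec_volume: np.ndarray
    sec_area_mid: np.ndarray
    sec_area_mature: np.ndarray

    @property
    def supplied(self) -> np.ndarray:
        return (
            self.plant_volume + self.newplant_volume
            + self.converted_volume + self.sec_volume
        )


@dataclass
class HarvestPlan:
    years: np.ndarray
    countries: dict[str, CountryPlan]


def _allocate_country(
    country: str,
    production: np.ndarray,
    years: np.ndarray,
    profile: CountryProfile,
    scenario: ScenarioConfig,
    conversion: ConversionTable,
    high_efficiency: float,
    newplant_allowance_ha_yr: float,
) -> CountryPlan:
    K = production.size
    R = profile.plantation_rotation
    plant_curve = _scaled_plantation_curve(profile, scenario)
    eff_sec = _secondary_efficiency(profile, scenario, high_efficiency)

    y_plant = _stand_yield(
        plant_curve, R, profile.slash_fraction_plantation,
        profile.harvest_efficiency, conversion,
    )
    y_mid = _stand_yield(
        profile.secondary_curve, profile.secondary_age_at_harvest,
        profile.slash_fraction_secondary, eff_sec, conversion,
    )
    y_mat = _stand_yield(
        profile.secondary_curve, profile.secondary_age_at_harvest + 40.0,
        profile.slash_fraction_secondary, eff_sec, conversion,
    )
    if production.max() > 0 and y_mid <= 0:
        raise AllocationError(f"{country}: secondary yield is zero but demand is positive")

    cap_volume = (profile.plantation_area_2010 / R) * y_plant if y_plant > 0 else 0.0

    plant_volume = np.zeros(K)
    plant_area = np.zeros(K)
    plant_new = np.zeros(K)
    npl_volume = np.zeros(K)
    npl_new = np.zeros(K)
    conv_volume = np.zeros(K)
    sec_volume = np.zeros(K)
    sec_mid = np.zeros(K)
    sec_mat = np.zeros(K)

    # slots cut in year i become available again in year i + R
    freed: deque[tuple[int, float]] = deque()
    free_pool = 0.0
    npl_freed: deque[tuple[int, float]] = deque()
    npl_free_pool = 0.0
    conv_pulses = np.zeros(K)           # scenario 2 supply returning in year i
    f_mat = scenario.mature_fraction

    for i in range(K):
        while freed and freed[0][0] <= i:
            free_pool += freed.popleft()[1]
        while npl_freed and npl_freed[0][0] <= i:
            npl_free_pool += npl_freed.popleft()[1]

        remaining = production[i]

        # 1) existing plantation estate
        v = min(remaining, cap_volume)
        plant_volume[i] = v
        remaining -= v
        if v > 0:
            a = clearcut_equivalent_area(v, y_plant)
            plant_area[i] = a
            reuse = min(a, free_pool)
            free_pool -= reuse
            plant_new[i] = a - reuse
            freed.append((i + R, a))

        # 2) scenario 4: new plantations mature R years after planting
        if newplant_allowance_ha_yr > 0 and i >= R:
            # cohorts planted in years 0..i-R have reached rotation age
            mature_area = newplant_allowance_ha_yr * (i - R + 1)
            npl_cap = (mature_area / R) * y_plant if y_plant > 0 else 0.0
            v = min(remaining, npl_cap)
            npl_volume[i] = v
            remaining -= v
            if v > 0:
                a = clearcut_equivalent_area(v, y_plant)
                reuse = min(a, npl_free_pool)
                npl_free_pool -= reuse
                npl_new[i] = a - reuse
                npl_freed.append((i + R, a))

        # 3) scenario 2: converted cohorts returning on plantation rotation
        v = min(remaining, conv_pulses[i])
        conv_volume[i] = v
        remaining -= v

        # 4) secondary forest for the rest
        if remaining > 0:
            sec_volume[i] = remaining
            if f_mat > 0:
                blended = (1.0 - f_mat) * y_mid + f_mat * y_mat
                a_tot = clearcut_equivalent_area(remaining, blended)
                sec_mid[i] = (1.0 - f_mat) * a_tot
                sec_mat[i] = f_mat * a_tot
            else:
                sec_mid[i] = clearcut_equivalent_area(remaining, y_mid)
            if scenario.regrow_secondary_as == "plantation":
                area_conv = sec_mid[i] + sec_mat[i]
                j = i + R
                while j < K:
                    conv_pulses[j] += area_conv * y_plant
                    j += R

    return CountryPlan(
        country=country,
        years=years,
        production=production,
        plant_volume=plant_volume,
        plant_area_harvested=plant_area,
        plant_new_area=plant_new,
        newplant_volume=npl_volume,
        newplant_new_area=npl_new,
        converted_volume=conv_volume,
        sec_volume=sec_volume,
        sec_area_mid=sec_mid,
        sec_area_mature=sec_mat,
    )


def allocate_supply(
    production: pd.DataFrame,
    profiles: Mapping[str, CountryProfile],
    scenario: ScenarioConfig,
    conversion: ConversionTable,
    *,
    high_efficiency: float = 0.8,
    newplant_weights: Mapping[str, float] | None = None,
) -> HarvestPlan:
    """Allocate required production (index years, columns countries) to forests.

    Plantations are harvested first, secondary forests as needed;
    scenario flags modify capacity, regrowth and age structure.  For
    scenario 4, ``newplant_weights`` distributes the global new-planting
    allowance across tropical countries.
    """
    years = production.index.to_numpy()
    plans: dict[str, CountryPlan] = {}
    weights = newplant_weights or {}
    total_w = sum(weights.get(c, 0.0) for c in production.columns) or 1.0
    for country in production.columns:
        profile = profiles[country]
        allowance = 0.0
        if scenario.new_tropical_plantations_ha_yr > 0 and profile.tropical:
            allowance = (
                scenario.new_tropical_plantations_ha_yr
                * weights.get(country, 0.0) / total_w
            )
        plans[country] = _allocate_country(
            country,
            production[country].to_numpy(dtype=float),
            years,
            profile,
            scenario,
            conversion,
            high_efficiency,
            allowance,
        )
    return HarvestPlan(years=years, countries=plans)


# ---------------------------------------------------------------------------
# scenario orchestration


@dataclass
class ScenarioResult:
    """Headline outputs of one scenario run (global, coverage-scaled)."""

    scenario: ScenarioConfig
    annualized_cost: float           # Gt CO2e yr^-1, methane-weighted
    cost_2010_level: float           # Gt CO2e yr^-1 at constant 2010 demand
    additional_cost: float           # Gt CO2e yr^-1 from demand growth
    substitution_savings: float      # Gt CO2e yr^-1, reported separately
    area_total_mha: float
    area_secondary_mha: float
    area_plantation_mha: float
    pdv_total_tc: float              # tC, Eq.-2 style aggregate
    pdv_total_co2e: float            # t CO2e, methane-weighted
    per_country: pd.DataFrame
    plan: HarvestPlan


def _demand_series(
    inputs: WorldInputs, scenario: ScenarioConfig, years: np.ndarray,
    constant_2010: bool,
) -> dict[str, pd.DataFrame]:
    """Per-product DataFrames (index year, columns country) of consumption."""
    out: dict[str, pd.DataFrame] = {}
    countries = list(inputs.demand_2010.index)
    for product in PRODUCTS:
        cols = {}
        for c in countries:
            c2010 = float(inputs.demand_2010.loc[c, product])
            c2050 = c2010 if constant_2010 else float(inputs.demand_2050.loc[c, product])
            series = interpolate_demand(c2010, c2050, inputs.start_year, inputs.end_year)
            cols[c] = series.loc[years].to_numpy()
        df = pd.DataFrame(cols, index=years)
        if product == "vslp_wfl" and scenario.wood_fuel_multiplier_2050 < 1.0 and not constant_2010:
            frac = (years - inputs.start_year) / (inputs.end_year - inputs.start_year)
            mult = 1.0 + (scenario.wood_fuel_multiplier_2050 - 1.0) * frac
            df = df.mul(mult, axis=0)
        out[product] = df
    return out


def _production_and_shares(
    inputs: WorldInputs, consumption: dict[str, pd.DataFrame], years: np.ndarray
) -> tuple[pd.DataFrame, dict[str, ProductShares], pd.DataFrame]:
    """Trade-adjusted roundwood requirement and per-country carbon shares.

    Returns (total production DataFrame year x country, scenario-average
    product shares per country, final-product carbon per year x country
    DataFrame pair packed as a dict-like frame for substitution).
    """
    countries = list(inputs.demand_2010.index)
    mis = {c: inputs.profiles[c].net_import_share for c in countries}
    exs = {c: inputs.profiles[c].export_share for c in countries}
    table = inputs.conversion

    prod_cons: dict[str, pd.DataFrame] = {}
    for product in PRODUCTS:
        rows = []
        for y in years:
            cons = consumption[product].loc[y]
            rows.append(apply_trade(cons, mis, exs))
        prod_cons[product] = pd.DataFrame(rows, index=years)

    total = pd.DataFrame(0.0, index=years, columns=countries)
    harvest_by_cat = {p: pd.DataFrame(0.0, index=years, columns=countries) for p in PRODUCTS}
    final_llp_c = pd.DataFrame(0.0, index=years, columns=countries)
    final_slp_c = pd.DataFrame(0.0, index=years, columns=countries)
    for c in countries:
        for y in years:
            mix = {p: float(prod_cons[p].loc[y, c]) for p in PRODUCTS}
            req = roundwood_from_consumption(mix, table)
            total.loc[y, c] = req["total"]
            for p in PRODUCTS:
                harvest_by_cat[p].loc[y, c] = req[p]
            final_llp_c.loc[y, c] = mix["llp"] * table.carbon_per_m3
            final_slp_c.loc[y, c] = mix["slp"] * table.pulp_share_virgin * table.carbon_per_m3

    shares: dict[str, ProductShares] = {}
    for c in countries:
        h_tot = float(total[c].sum())
        if h_tot <= 0:
            shares[c] = ProductShares(llp=0.0, slp=0.0, vslp_wfl=0.0, vslp_ind=1.0)
            continue
        s_llp = float(final_llp_c[c].sum()) / (h_tot * table.carbon_per_m3)
        s_slp = float(final_slp_c[c].sum()) / (h_tot * table.carbon_per_m3)
        s_wfl = float(harvest_by_cat["vslp_wfl"][c].sum()) / h_tot
        s_ind = 1.0 - s_llp - s_slp - s_wfl  # processing waste + extra IND harvest
        shares[c] = ProductShares(llp=s_llp, slp=s_slp, vslp_wfl=s_wfl, vslp_ind=s_ind)

    substitution_c = pd.DataFrame(
        {
            "llp_final_c": final_llp_c.sum(axis=0),
            "wfl_c": {
                c: float(consumption["vslp_wfl"][c].sum()) * table.carbon_per_m3
                for c in countries
            },
        }
    )
    return total, shares, substitution_c


def _country_pdvs(
    profile: CountryProfile,
    scenario: ScenarioConfig,
    shares: ProductShares,
    inputs: WorldInputs,
) -> dict[str, tuple[float, float]]:
    """(tC, tCO2e) per-hectare harvest-year-equivalent costs by stand kind."""
    spec = inputs.discount
    horizon = spec.N + 1
    eff_sec = _secondary_efficiency(profile, scenario, inputs.high_efficiency)
    plant_curve = _scaled_plantation_curve(profile, scenario)
    common = dict(
        rootshoot=profile.rootshoot,
        product_shares=shares,
        half_lives=inputs.half_lives,
        methane=inputs.methane,
    )

    def value(traj) -> tuple[float, float]:
        return (
            pdv(traj.delta_series, spec),
            pdv(delta_co2e_series(traj, inputs.methane), spec),
        )

    out: dict[str, tuple[float, float]] = {}

    sec_params = StandParams(
        curve=profile.secondary_curve,
        slash_fraction=profile.slash_fraction_secondary,
        rotation=profile.plantation_rotation if scenario.regrow_secondary_as == "plantation" else None,
        regrow_curve=plant_curve if scenario.regrow_secondary_as == "plantation" else None,
        **common,
    )
    out["secondary_mid"] = value(
        simulate_stand(
            sec_params, horizon, profile.secondary_age_at_harvest,
            regrow_as=scenario.regrow_secondary_as, efficiency=eff_sec,
        )
    )
    if scenario.mature_fraction > 0:
        out["secondary_mature"] = value(
            simulate_stand(
                sec_params, horizon, profile.secondary_age_at_harvest + 40.0,
                regrow_as=scenario.regrow_secondary_as, efficiency=eff_sec,
            )
        )

    plant_params = StandParams(
        curve=plant_curve,
        slash_fraction=profile.slash_fraction_plantation,
        rotation=profile.plantation_rotation,
        **common,
    )
    out["plantation"] = value(
        simulate_stand(
            plant_params, horizon, float(profile.plantation_rotation),
            regrow_as="secondary", efficiency=profile.harvest_efficiency,
        )
    )
    if scenario.new_tropical_plantations_ha_yr > 0 and profile.tropical:
        # cohort valued from planting: grows R years, then rotates; the
        # counterfactual is secondary regrowth on the same land from age 0
        out["new_plantation"] = value(
            simulate_stand(
                plant_params, horizon, float(profile.plantation_rotation),
                regrow_as="secondary", efficiency=profile.harvest_efficiency,
                first_harvest_year=profile.plantation_rotation,
                cf_curve=profile.secondary_curve, cf_start_age=0.0,
            )
        )
    return out


def _run_once(
    scenario: ScenarioConfig, inputs: WorldInputs, constant_2010: bool
) -> tuple[float, float, HarvestPlan, pd.DataFrame, pd.DataFrame]:
    years = np.arange(inputs.start_year, inputs.start_year + inputs.n_harvest_years)
    consumption = _demand_series(inputs, scenario, years, constant_2010)
    production, shares, substitution_c = _production_and_shares(inputs, consumption, years)

    weights = {
        c: float(production[c].sum())
        for c in production.columns
        if inputs.profiles[c].tropical
    }
    plan = allocate_supply(
        production, inputs.profiles, scenario, inputs.conversion,
        high_efficiency=inputs.high_efficiency, newplant_weights=weights,
    )

    pdv_tc_total = 0.0
    pdv_co2e_total = 0.0
    rows = []
    for c, cp in plan.countries.items():
        vals = _country_pdvs(inputs.profiles[c], scenario, shares[c], inputs)
        sec_area = cp.sec_area_mid + cp.sec_area_mature
        # area-weighted secondary PDV per year (mid + mature mix)
        tc_mid, co2e_mid = vals["secondary_mid"]
        tc_mat, co2e_mat = vals.get("secondary_mature", (0.0, 0.0))
        sec_tc = cp.sec_area_mid * tc_mid + cp.sec_area_mature * tc_mat
        sec_co2e = cp.sec_area_mid * co2e_mid + cp.sec_area_mature * co2e_mat

        tc_pl, co2e_pl = vals["plantation"]
        pl_tc = cp.plant_new_area * tc_pl
        pl_co2e = cp.plant_new_area * co2e_pl
        if "new_plantation" in vals:
            tc_np, co2e_np = vals["new_plantation"]
            pl_tc = pl_tc + cp.newplant_new_area * tc_np
            pl_co2e = pl_co2e + cp.newplant_new_area * co2e_np

        c_tc = float(sec_tc.sum() + pl_tc.sum())
        c_co2e = float(sec_co2e.sum() + pl_co2e.sum())
        pdv_tc_total += c_tc
        pdv_co2e_total += c_co2e
        rows.append(
            {
                "country": c,
                "pdv_tc": c_tc,
                "pdv_co2e": c_co2e,
                "secondary_area_ha": float(sec_area.sum()),
                "plantation_new_area_ha": float(cp.plant_new_area.sum() + cp.newplant_new_area.sum()),
                "production_m3": float(cp.production.sum()),
            }
        )
    per_country = pd.DataFrame(rows).set_index("country")
    return pdv_tc_total, pdv_co2e_total, plan, per_country, substitution_c


def run_scenario(scenario: ScenarioConfig | int, inputs: WorldInputs) -> ScenarioResult:
    """Run one supply scenario end to end.

    Orchestrates demand interpolation, trade, harvest allocation, stand
    simulation and discounting; returns coverage-scaled global results.
    The cost at 2010 demand comes from an identical run with consumption
    held at 2010 levels; the difference is the cost of demand growth.
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    K = inputs.n_harvest_years

    pdv_tc, pdv_co2e, plan, per_country, subst_c = _run_once(scenario, inputs, False)
    pdv_tc_2010, pdv_co2e_2010, *_ = _run_once(scenario, inputs, True)

    def to_gt_per_yr(t_co2e: float) -> float:
        return scale_global(t_co2e, inputs.coverage) / K / 1e9

    annualized = to_gt_per_yr(pdv_co2e)
    at_2010 = to_gt_per_yr(pdv_co2e_2010)

    subst_tc = 0.0
    for c, row in subst_c.iterrows():
        factors = dc_replace(
            inputs.substitution,
            construction_share=inputs.profiles[c].construction_share,
        )
        subst_tc += row["llp_final_c"] * factors.construction_share * factors.construction
        subst_tc += row["wfl_c"] * factors.wood_fuel
    substitution = to_gt_per_yr(subst_tc * CO2_PER_C)

    sec_area = sum(
        float((cp.sec_area_mid + cp.sec_area_mature).sum())
        for cp in plan.countries.values()
    )
    pl_area = sum(
        float(cp.plant_new_area.sum() + cp.newplant_new_area.sum())
        for cp in plan.countries.values()
    )
    sec_area_mha = scale_global(sec_area, inputs.coverage) / 1e6
    pl_area_mha = scale_global(pl_area, inputs.coverage) / 1e6

    return ScenarioResult(
        scenario=scenario,
        annualized_cost=annualized,
        cost_2010_level=at_2010,
        additional_cost=annualized - at_2010,
        substitution_savings=substitution,
        area_total_mha=sec_area_mha + pl_area_mha,
        area_secondary_mha=sec_area_mha,
        area_plantation_mha=pl_area_mha,
        pdv_total_tc=scale_global(pdv_tc, inputs.coverage),
        pdv_total_co2e=scale_global(pdv_co2e, inputs.coverage),
        per_country=per_country,
        plan=plan,
    )
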