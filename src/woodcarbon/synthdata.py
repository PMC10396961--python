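"""Synthetic country profiles, demand panels and stand fixtures.

Everything the pipeline consumes — growth-rate bands, slash rates,
rotations, plantation areas, trade shares, FAOSTAT-like demand panels —
can be generated here so the package builds and tests without any
download.  The generated world is internally consistent (shares sum to
one, trade balances, growth bands admit a Monod fit, panel consumption
lies on a known log-linear surface) and sized to resemble the study
conditions: ~30 countries covering 80 % of world wood production, a
1961–2020 historical panel, and a 2010–2050 projection window.  It does
not attempt to reproduce the statistical texture of real FAOSTAT data.

A single root seed fans out to named substreams, one per table, so
adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .demand import REGRESSION_PRODUCTS, fit_fe_model, project_consumption
from .growth import GrowthBands, MonodCurve, RootShootParams, fit_monod
from .products import ConversionTable, LandfillParams, ProductShares
from .stand import HalfLives, StandParams
from .supply import CountryProfile, WorldInputs
from .valuation import DiscountSpec, SubstitutionFactors

__all__ = [
    "SynthSpec",
    "gen_demand_panel",
    "gen_growth_factors",
    "gen_country_profiles",
    "gen_stand_fixture",
    "build_world",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic world.

    ``true_betas`` maps product -> (beta_pop, beta_gdp_pc, beta_time);
    these are the generating elasticities the demand panel is built on,
    returned alongside so recovery tests can compare against truth.
    """

    seed: int = 0
    n_countries: int = 30
    year_range: tuple[int, int] = (1961, 2020)
    noise_sd: float = 0.4
    tropical_fraction: float = 0.4
    importer_fraction: float = 0.35
    # per-country 2010 roundwood demand (lognormal median); sized so the
    # 30 covered countries produce ~3 billion m3, i.e. 80 % of a
    # 3.7-billion-m3 world harvest
    mean_total_demand_m3: float = 6.7e7
    true_betas: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "llp": (0.9, 0.7, 0.004),
            "slp": (0.8, 0.9, -0.010),
            "vslp_wfl": (1.0, -0.3, -0.005),
        }
    )

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: independent of other streams under one seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])

    def country_names(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_countries)]


# product split of total roundwood demand, jittered per country
_BASE_SPLIT = {"llp": 0.30, "slp": 0.16, "vslp_wfl": 0.52, "vslp_ind": 0.02}


def _country_macro(spec: SynthSpec) -> pd.DataFrame:
    """Per-country 2010 macro state and growth rates (deterministic per seed)."""
    rng = spec.rng("macro")
    names = spec.country_names()
    pop0 = rng.lognormal(mean=np.log(3e7), sigma=1.0, size=len(names))
    gdp0 = rng.lognormal(mean=np.log(8000.0), sigma=1.0, size=len(names))
    g_pop = rng.uniform(0.002, 0.015, size=len(names))
    g_gdp = rng.uniform(0.008, 0.030, size=len(names))
    developed = gdp0 > np.median(gdp0)
    total0 = rng.lognormal(
        mean=np.log(spec.mean_total_demand_m3), sigma=0.9, size=len(names)
    )
    split_jitter = rng.uniform(0.7, 1.3, size=(len(names), 4))
    splits = np.array([_BASE_SPLIT[p] for p in ("llp", "slp", "vslp_wfl", "vslp_ind")])
    shares = splits * split_jitter
    shares = shares / shares.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        {
            "country": names,
            "pop_2010": pop0,
            "gdp_pc_2010": gdp0,
            "g_pop": g_pop,
            "g_gdp": g_gdp,
            "developed": developed,
            "total_demand_2010": total0,
            "share_llp": shares[:, 0],
            "share_slp": shares[:, 1],
            "share_vslp_wfl": shares[:, 2],
            "share_vslp_ind": shares[:, 3],
        }
    ).set_index("country")


def gen_demand_panel(spec: SynthSpec) -> tuple[pd.DataFrame, dict]:
    """FAOSTAT-like long panel with known generating coefficients.

    Consumption follows ``log C = alpha_i + b_pop log P + b_gdp log g +
    b_t (year-2000) + e`` with country intercepts anchored so that each
    country's 2010 consumption matches its drawn base demand.  Returns
    ``(panel, truth)`` where ``truth`` holds the generating betas and
    noise level.
    """
    macro = _country_macro(spec)
    rng = spec.rng("panel")
    y0, y1 = spec.year_range
    years = np.arange(y0, y1 + 1)
    rows = []
    for country, m in macro.iterrows():
        t = years - 2010.0
        pop = m["pop_2010"] * np.exp(m["g_pop"] * t)
        # small multiplicative noise keeps GDP from being collinear with time
        gdp = m["gdp_pc_2010"] * np.exp(m["g_gdp"] * t) * np.exp(
            rng.normal(0.0, 0.02, size=years.size)
        )
        for product in REGRESSION_PRODUCTS:
            b_pop, b_gdp, b_t = spec.true_betas[product]
            base = m["total_demand_2010"] * m[f"share_{product}"]
            alpha = (
                np.log(base)
                - b_pop * np.log(m["pop_2010"])
                - b_gdp * np.log(m["gdp_pc_2010"])
                - b_t * 10.0
            )
            noise = rng.normal(0.0, spec.noise_sd, size=years.size)
            cons = np.exp(
                alpha
                + b_pop * np.log(pop)
                + b_gdp * np.log(gdp)
                + b_t * (years - 2000.0)
                + noise
            )
            for yr, c, p, g in zip(years, cons, pop, gdp):
                rows.append(
                    {
                        "country": country,
                        "year": int(yr),
                        "product": product,
                        "consumption": float(c),
                        "gdp_pc": float(g),
                        "population": float(p),
                        "developed": bool(m["developed"]),
                    }
                )
    panel = pd.DataFrame(rows)
    truth = {"betas": dict(spec.true_betas), "noise_sd": spec.noise_sd}
    return panel, truth


def gen_growth_factors(spec: SynthSpec) -> pd.DataFrame:
    """Exogenous 2050/2010 population and GDP-per-capita growth factors."""
    macro = _country_macro(spec)
    return pd.DataFrame(
        {
            "pop_factor": np.exp(macro["g_pop"] * 40.0),
            "gdp_factor": np.exp(macro["g_gdp"] * 40.0),
        },
        index=macro.index,
    )


def gen_country_profiles(spec: SynthSpec) -> dict[str, CountryProfile]:
    """Country supply profiles with all type invariants satisfied.

    Growth bands always decline with age (Monod-feasible), efficiencies
    lie in (0, 1], product shares are taken from demand at run time, and
    export shares are normalized so trade balances globally.
    """
    macro = _country_macro(spec)
    rng = spec.rng("profiles")
    n = spec.n_countries
    tropical = rng.random(n) < spec.tropical_fraction

    sec_young = rng.uniform(2.5, 7.0, size=n)
    sec_old = sec_young * rng.uniform(0.30, 0.65, size=n)
    pl_young = rng.uniform(5.0, 12.0, size=n)
    pl_old = pl_young * rng.uniform(0.30, 0.60, size=n)
    rotation = np.where(
        tropical, rng.integers(8, 16, size=n), rng.integers(15, 31, size=n)
    )
    sec_age = rng.integers(35, 56, size=n).astype(float)
    eff = np.where(
        tropical, rng.uniform(0.35, 0.60, size=n), rng.uniform(0.55, 0.90, size=n)
    )
    slash_sec = rng.uniform(0.20, 0.45, size=n)
    slash_pl = rng.uniform(0.15, 0.30, size=n)
    constr = rng.uniform(0.3, 0.8, size=n)

    importer = rng.random(n) < spec.importer_fraction
    import_share = np.where(importer, rng.uniform(0.05, 0.40, size=n), 0.0)
    export_w = np.where(~importer, macro["total_demand_2010"].to_numpy(), 0.0)
    export_share = export_w / export_w.sum()

    # plantation estates sized to supply a 10-60 % slice of 2010 demand
    plant_cover = rng.uniform(0.10, 0.60, size=n)

    profiles: dict[str, CountryProfile] = {}
    conv = ConversionTable()
    for i, country in enumerate(macro.index):
        pl_curve = fit_monod(GrowthBands(pl_young[i], pl_old[i]))
        sec_curve = fit_monod(GrowthBands(sec_young[i], sec_old[i]))
        y_plant = (
            pl_curve.agb(float(rotation[i])) * (1 - slash_pl[i]) * eff[i]
            / conv.carbon_per_m3
        )
        demand = float(macro.loc[country, "total_demand_2010"])
        area = plant_cover[i] * demand * rotation[i] / y_plant
        profiles[country] = CountryProfile(
            name=country,
            tropical=bool(tropical[i]),
            plantation_area_2010=float(area),
            plantation_curve=pl_curve,
            secondary_curve=sec_curve,
            plantation_rotation=int(rotation[i]),
            secondary_age_at_harvest=float(sec_age[i]),
            harvest_efficiency=float(eff[i]),
            slash_fraction_secondary=float(slash_sec[i]),
            slash_fraction_plantation=float(slash_pl[i]),
            net_import_share=float(import_share[i]),
            export_share=float(export_share[i]),
            construction_share=float(constr[i]),
        )
    return profiles


def gen_stand_fixture(spec: SynthSpec) -> tuple[StandParams, float, float, pd.DataFrame]:
    """A tiny integer-friendly stand plus an expectation sheet.

    Returns ``(params, efficiency, first_harvest_age, expected)`` where
    ``expected`` tabulates pool values for simulation years 0-2 computed
    by a deliberately plain straight-line calculation, independent of the
    stand simulator's own loop.
    """
    curve = MonodCurve(a_max=200.0, k_half=20.0)
    rs = RootShootParams(coefficient=0.25, exponent=1.0)  # linear: bgb = agb/4
    shares = ProductShares(llp=0.5, slp=0.25, vslp_wfl=0.25, vslp_ind=0.0)
    hl = HalfLives(slash=1.0, roots=1.0, llp=2.0, slp=1.0, landfill=2.0)
    lf = LandfillParams(landfill_fraction_of_llp_decay=0.5, methane_fraction=0.5, gwp100_ch4=28.0)
    params = StandParams(
        curve=curve, rootshoot=rs, slash_fraction=0.2,
        product_shares=shares, half_lives=hl, methane=lf,
    )
    efficiency = 1.0
    age = 20.0  # AGB = 100 by half-saturation

    # --- straight-line expectation sheet (plain arithmetic, no loops) ---
    agb0 = 200.0 * age / (20.0 + age)          # 100
    bgb0 = agb0 / 4.0                          # 25
    slash0 = 0.2 * agb0                        # 20
    recovered = 0.8 * agb0                     # 80
    llp0, slp0 = 0.5 * recovered, 0.25 * recovered   # 40, 20
    emit0 = 0.25 * recovered                   # burned VSLP = 20
    year0 = dict(age=0.0, live_agb=0.0, live_bgb=0.0, slash=slash0, dead_roots=bgb0,
                 llp_stock=llp0, slp_stock=slp0, landfill_stock=0.0,
                 cumulative_emitted=emit0)

    # year 1: decay (slash & roots & slp halve; llp retains 2^-0.5), regrow age 1
    r2 = 2.0 ** -0.5
    slash1 = slash0 * 0.5
    roots1 = bgb0 * 0.5
    slp1 = slp0 * 0.5
    llp1 = llp0 * r2
    llp_rel = llp0 - llp1
    landfill1 = 0.5 * llp_rel
    emit1 = emit0 + slash0 * 0.5 + bgb0 * 0.5 + slp0 * 0.5 + (llp_rel - landfill1)
    agb1 = 200.0 * 1.0 / 21.0
    year1 = dict(age=1.0, live_agb=agb1, live_bgb=agb1 / 4.0, slash=slash1,
                 dead_roots=roots1, llp_stock=llp1, slp_stock=slp1,
                 landfill_stock=landfill1, cumulative_emitted=emit1)

    # year 2: decay again (landfill retains 2^-0.5), regrow age 2
    slash2 = slash1 * 0.5
    roots2 = roots1 * 0.5
    slp2 = slp1 * 0.5
    llp2 = llp1 * r2
    llp_rel2 = llp1 - llp2
    landfill_in = 0.5 * llp_rel2
    landfill_kept = landfill1 * r2
    landfill2 = landfill_kept + landfill_in
    emit2 = emit1 + slash1 * 0.5 + roots1 * 0.5 + slp1 * 0.5 \
        + (llp_rel2 - landfill_in) + (landfill1 - landfill_kept)
    agb2 = 200.0 * 2.0 / 22.0
    year2 = dict(age=2.0, live_agb=agb2, live_bgb=agb2 / 4.0, slash=slash2,
                 dead_roots=roots2, llp_stock=llp2, slp_stock=slp2,
                 landfill_stock=landfill2, cumulative_emitted=emit2)

    expected = pd.DataFrame([year0, year1, year2], index=[0, 1, 2])
    return params, efficiency, age, expected


def build_world(spec: SynthSpec, project: bool = True) -> WorldInputs:
    """Assemble a complete :class:`WorldInputs` from the generators.

    2010 demand is the 2006-2014 mean of the synthetic panel (plus a
    waste-sized ``vslp_ind`` column); 2050 demand comes from fitting the
    fixed-effects models on the panel and projecting with the synthetic
    growth factors (``project=False`` keeps demand flat for cheap tests).
    """
    profiles = gen_country_profiles(spec)
    panel, _ = gen_demand_panel(spec)
    factors = gen_growth_factors(spec)
    macro = _country_macro(spec)

    base = (
        panel[(panel["year"] >= 2006) & (panel["year"] <= 2014)]
        .groupby(["country", "product"])["consumption"]
        .mean()
        .unstack("product")
    )
    base["vslp_ind"] = (
        macro["total_demand_2010"] * macro["share_vslp_ind"]
    ).reindex(base.index)
    base = base[list(("llp", "slp", "vslp_wfl", "vslp_ind"))]

    if project:
        models = {}
        for product in REGRESSION_PRODUCTS:
            for group in ("developed", "developing"):
                models[(product, group)] = fit_fe_model(panel, product, group, with_time=True)
        dem_2050 = base.copy()
        for country in base.index:
            group = "developed" if bool(macro.loc[country, "developed"]) else "developing"
            for product in REGRESSION_PRODUCTS:
                dem_2050.loc[country, product] = project_consumption(
                    models[(product, group)],
                    float(base.loc[country, product]),
                    float(factors.loc[country, "pop_factor"]),
                    float(factors.loc[country, "gdp_factor"]),
                )
        growth = dem_2050[list(REGRESSION_PRODUCTS)].sum(axis=1) / base[
            list(REGRESSION_PRODUCTS)
        ].sum(axis=1)
        dem_2050["vslp_ind"] = base["vslp_ind"] * growth
    else:
        dem_2050 = base.copy()

    return WorldInputs(
        profiles=profiles,
        demand_2010=base,
        demand_2050=dem_2050,
        conversion=ConversionTable(),
        half_lives=HalfLives(),
        methane=LandfillParams(),
        discount=DiscountSpec(),
        substitution=SubstitutionFactors(),
    )
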