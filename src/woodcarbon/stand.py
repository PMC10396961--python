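"""Per-hectare carbon-pool bookkeeping under harvest and no-harvest paths.

A harvested hectare is tracked year by year across storage pools: live
above- and below-ground biomass, slash (felled wood left on site), dead
roots, long- and short-lived product stocks, and landfills.  The
counterfactual path lets the same stand keep growing unharvested.  The
carbon cost of the harvest in any year is the gap between carbon stored
on the counterfactual path and carbon stored on the harvest path; annual
emissions (positive) or removals (negative) are the first differences of
that gap.

Timing conventions (discrete annual steps):

* a harvest clears the live pools at the start of the year; the felled
  carbon is partitioned into slash, dead roots, product stocks and an
  immediate emission (the very-short-lived share is burned at once);
* regrowth of the new stand begins the following year;
* dead and product pools decay first-order with per-step retention
  ``2**(-1/half_life)``, starting the year after they are created.

Carbon is conserved exactly: each year the change in total accounted
carbon (all pools plus cumulative emissions) equals new live growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .growth import MonodCurve, RootShootParams, agb_at_age, bgb_from_agb
from .products import CO2_PER_C, CH4_PER_C, LandfillParams, ProductShares

__all__ = [
    "HalfLives",
    "PoolState",
    "StandParams",
    "Trajectory",
    "decay_step",
    "harvest_event",
    "simulate_stand",
    "annual_atmosphere_delta",
    "delta_co2e_series",
]


@dataclass(frozen=True)
class HalfLives:
    """Per-pool half-lives in years (may be ``math.inf`` for inert pools)."""

    slash: float = 10.0
    roots: float = 10.0
    llp: float = 35.0
    slp: float = 2.0
    landfill: float = 29.0

    def __post_init__(self) -> None:
        for name in ("slash", "roots", "llp", "slp", "landfill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"half-life {name}={getattr(self, name)} must be positive")


@dataclass(frozen=True)
class PoolState:
    """Carbon stocks (tC ha^-1) at the end of one simulated year."""

    age: float = 0.0
    live_agb: float = 0.0
    live_bgb: float = 0.0
    slash: float = 0.0
    dead_roots: float = 0.0
    llp_stock: float = 0.0
    slp_stock: float = 0.0
    landfill_stock: float = 0.0
    cumulative_emitted: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "live_agb", "live_bgb", "slash", "dead_roots",
            "llp_stock", "slp_stock", "landfill_stock",
        ):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"pool {name} is negative: {getattr(self, name)}")

    @property
    def total_stored(self) -> float:
        """Carbon held in all storage pools (excludes emitted carbon)."""
        return (
            self.live_agb + self.live_bgb + self.slash + self.dead_roots
            + self.llp_stock + self.slp_stock + self.landfill_stock
        )


@dataclass(frozen=True)
class StandParams:
    """Parameters of one simulated stand."""

    curve: MonodCurve
    rootshoot: RootShootParams
    slash_fraction: float
    product_shares: ProductShares
    half_lives: HalfLives = field(default_factory=HalfLives)
    rotation: int | None = None
    thinning_schedule: tuple[tuple[int, float], ...] = ()
    methane: LandfillParams = field(default_factory=LandfillParams)
    regrow_curve: MonodCurve | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.slash_fraction <= 1.0:
            raise ValueError(f"slash_fraction={self.slash_fraction} outside [0, 1]")
        if self.rotation is not None and self.rotation <= 0:
            raise ValueError(f"rotation must be positive, got {self.rotation}")
        for offset, frac in self.thinning_schedule:
            if offset <= 0 or not 0.0 <= frac <= 1.0:
                raise ValueError(f"invalid thinning entry ({offset}, {frac})")


@dataclass
class Trajectory:
    """Yearly pool states on both paths and the atmospheric-change series.

    ``delta_series[t]`` is the change in the storage gap (counterfactual
    minus harvest path) during year ``t``; positive values are emissions.
    ``ch4_c_series`` is the carbon leaving landfills as methane each year
    on the harvest path (tC ha^-1), used for CO2e weighting.
    """

    harvest_path: list[PoolState]
    counterfactual_path: list[PoolState]
    delta_series: np.ndarray
    ch4_c_series: np.ndarray
    growth_series: np.ndarray
    cf_growth_series: np.ndarray
    harvest_base_storage: float
    cf_base_storage: float

    def __post_init__(self) -> None:
        n = len(self.harvest_path)
        if not (len(self.counterfactual_path) == n == len(self.delta_series)):
            raise ValueError("trajectory paths and delta series must have equal length")

    @property
    def storage_gap(self) -> np.ndarray:
        """Counterfactual-minus-harvest stored carbon, relative to year -1."""
        h = np.array([s.total_stored for s in self.harvest_path]) - self.harvest_base_storage
        c = np.array([s.total_stored for s in self.counterfactual_path]) - self.cf_base_storage
        return c - h


def decay_step(stock: float, half_life: float) -> tuple[float, float]:
    """One annual first-order decay step.

    Returns ``(remaining, released)`` with ``remaining = stock *
    2**(-1/half_life)`` so the stock halves after exactly ``half_life``
    annual steps; ``remaining + released == stock`` exactly.
    """
    if stock < 0:
        raise ValueError(f"stock must be non-negative, got {stock}")
    if not half_life > 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    remaining = stock * 2.0 ** (-1.0 / half_life)
    return remaining, stock - remaining


def _partition_felled(
    agb: float, bgb: float, params: StandParams, efficiency: float
) -> tuple[float, float, dict[str, float], float]:
    """Split felled biomass into slash, dead roots, product flows, emission.

    ``slash_fraction`` of felled above-ground biomass stays on site; the
    unrecovered part of the remainder (harvest losses, 1-efficiency) also
    stays as slash.  Recovered wood splits across product categories; the
    very-short-lived share is burned immediately.  The emission is the
    exact residual so carbon closes to machine precision.
    """
    shares = params.product_shares
    slash_add = agb * params.slash_fraction
    removable = agb - slash_add
    recovered = removable * efficiency
    slash_add += removable - recovered
    flows = {
        "llp": recovered * shares.llp,
        "slp": recovered * shares.slp,
        "vslp_wfl": recovered * shares.vslp_wfl,
        "vslp_ind": recovered * shares.vslp_ind,
    }
    emitted = recovered - flows["llp"] - flows["slp"]  # burned VSLP, exact residual
    return slash_add, bgb, flows, emitted


def harvest_event(
    state: PoolState, params: StandParams, efficiency: float
) -> tuple[PoolState, dict[str, float]]:
    """Clear-cut the live pools of ``state`` and repartition the carbon.

    Live above-ground biomass splits into slash (``slash_fraction`` plus
    harvest losses), recovered wood by product share (very-short-lived
    wood burned as an immediate emission); live roots move to the dead
    root pool.  Returns the post-harvest state (age reset to 0) and the
    recovered product flows in tC ha^-1.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    if state.live_agb == 0.0 and state.live_bgb == 0.0:
        return replace(state, age=0.0), {p: 0.0 for p in ("llp", "slp", "vslp_wfl", "vslp_ind")}
    slash_add, roots_add, flows, emitted = _partition_felled(
        state.live_agb, state.live_bgb, params, efficiency
    )
    new_state = replace(
        state,
        age=0.0,
        live_agb=0.0,
        live_bgb=0.0,
        slash=state.slash + slash_add,
        dead_roots=state.dead_roots + roots_add,
        llp_stock=state.llp_stock + flows["llp"],
        slp_stock=state.slp_stock + flows["slp"],
        landfill_stock=state.landfill_stock,
        cumulative_emitted=state.cumulative_emitted + emitted,
    )
    return new_state, flows


def _simulate_path(
    params: StandParams,
    horizon: int,
    initial_age: float,
    harvest_years: frozenset[int],
    regrow_curve: MonodCurve | None,
    efficiency: float,
    curve: MonodCurve,
) -> tuple[list[PoolState], np.ndarray, np.ndarray]:
    """March one path forward; returns (states, ch4_series, growth_series)."""
    hl = params.half_lives
    lf = params.methane
    rs = params.rootshoot

    age = float(initial_age)
    agb = agb_at_age(curve, age)
    bgb = bgb_from_agb(rs, agb)
    slash = roots = llp = slp = landfill = 0.0
    cum_emitted = 0.0
    growing_curve: MonodCurve | None = curve

    states: list[PoolState] = []
    ch4 = np.zeros(horizon)
    growth = np.zeros(horizon)

    for t in range(horizon):
        emitted = 0.0
        # 1) decay pools carried over from last year
        slash, rel = decay_step(slash, hl.slash)
        emitted += rel
        roots, rel = decay_step(roots, hl.roots)
        emitted += rel
        slp, rel = decay_step(slp, hl.slp)
        emitted += rel
        # landfill decays before receiving this year's LLP inflow so that
        # newly created stock starts decaying the following year
        landfill, rel = decay_step(landfill, hl.landfill)
        ch4[t] = rel * lf.methane_fraction
        emitted += rel
        llp, rel = decay_step(llp, hl.llp)
        to_landfill = rel * lf.landfill_fraction_of_llp_decay
        landfill += to_landfill
        emitted += rel - to_landfill

        harvested = t in harvest_years
        if harvested:
            slash_add, roots_add, _flows, vslp_emit = _partition_felled(
                agb, bgb, params, efficiency
            )
            slash += slash_add
            roots += roots_add
            llp += _flows["llp"]
            slp += _flows["slp"]
            emitted += vslp_emit
            agb = bgb = 0.0
            age = 0.0
            growing_curve = regrow_curve
        else:
            # thinning at configured stand ages (same land, no new area)
            for offset, frac in params.thinning_schedule:
                if age == offset and agb > 0.0:
                    thin_agb = agb * frac
                    thin_bgb = bgb * frac
                    agb -= thin_agb
                    bgb -= thin_bgb
                    slash_add, roots_add, _flows, vslp_emit = _partition_felled(
                        thin_agb, thin_bgb, params, efficiency
                    )
                    slash += slash_add
                    roots += roots_add
                    llp += _flows["llp"]
                    slp += _flows["slp"]
                    emitted += vslp_emit
            # 2) growth along the stand's curve; regrowth starts the year
            #    after a harvest because age was reset to 0 then
            if growing_curve is not None:
                agb_inc = agb_at_age(growing_curve, age + 1) - agb_at_age(growing_curve, age)
                bgb_target_inc = bgb_from_agb(rs, agb + agb_inc) - bgb_from_agb(rs, agb)
                agb += agb_inc
                bgb += bgb_target_inc
                growth[t] = agb_inc + bgb_target_inc
            age += 1.0

        cum_emitted += emitted
        states.append(
            PoolState(
                age=age,
                live_agb=agb,
                live_bgb=bgb,
                slash=slash,
                dead_roots=roots,
                llp_stock=llp,
                slp_stock=slp,
                landfill_stock=landfill,
                cumulative_emitted=cum_emitted,
            )
        )
    return states, ch4, growth


def simulate_stand(
    params: StandParams,
    horizon: int,
    first_harvest_age: float,
    regrow_as: Literal["plantation", "secondary", "none"] = "secondary",
    *,
    efficiency: float = 1.0,
    first_harvest_year: int = 0,
    cf_curve: MonodCurve | None = None,
    cf_start_age: float | None = None,
    harvest: bool = True,
) -> Trajectory:
    """Simulate one hectare under harvest and no-harvest paths.

    The stand enters the simulation ``first_harvest_year`` years before
    its first clear-cut (0 = harvested immediately at
    ``first_harvest_age``).  After harvest it regrows along its own curve
    (``"secondary"``), along ``params.regrow_curve`` (``"plantation"``,
    e.g. conversion scenarios) or not at all (``"none"``); repeat
    harvests follow ``params.rotation`` if set.  The counterfactual stand
    grows unharvested from ``cf_start_age`` (default: the stand's age at
    the start of the simulation) along ``cf_curve`` (default: the stand's
    own curve).

    Returns a :class:`Trajectory` whose ``delta_series`` holds the annual
    atmospheric change attributable to the harvest (positive = emission).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if first_harvest_year < 0 or first_harvest_year >= horizon and harvest:
        raise ValueError(
            f"first_harvest_year={first_harvest_year} outside [0, horizon)"
        )
    initial_age = first_harvest_age - first_harvest_year
    if initial_age < 0:
        raise ValueError(
            "first_harvest_age must be >= first_harvest_year "
            f"(got {first_harvest_age} < {first_harvest_year})"
        )

    if harvest:
        years = {first_harvest_year}
        if params.rotation:
            y = first_harvest_year + params.rotation
            while y < horizon:
                years.add(y)
                y += params.rotation
        harvest_years = frozenset(years)
    else:
        harvest_years = frozenset()

    if regrow_as == "secondary":
        regrow_curve: MonodCurve | None = params.curve
    elif regrow_as == "plantation":
        regrow_curve = params.regrow_curve or params.curve
    elif regrow_as == "none":
        regrow_curve = None
    else:
        raise ValueError(f"unknown regrow_as {regrow_as!r}")

    h_states, ch4, growth = _simulate_path(
        params, horizon, initial_age, harvest_years, regrow_curve, efficiency, params.curve
    )

    cfc = cf_curve or params.curve
    cf_age0 = initial_age if cf_start_age is None else cf_start_age
    cf_states, _cf_ch4, cf_growth = _simulate_path(
        params, horizon, cf_age0, frozenset(), None, efficiency, cfc
    )

    rs = params.rootshoot
    h_base = agb_at_age(params.curve, initial_age) + bgb_from_agb(
        rs, agb_at_age(params.curve, initial_age)
    )
    cf_base = agb_at_age(cfc, cf_age0) + bgb_from_agb(rs, agb_at_age(cfc, cf_age0))

    h_store = np.array([s.total_stored for s in h_states]) - h_base
    cf_store = np.array([s.total_stored for s in cf_states]) - cf_base
    gap = cf_store - h_store
    delta = np.diff(gap, prepend=0.0)

    return Trajectory(
        harvest_path=h_states,
        counterfactual_path=cf_states,
        delta_series=delta,
        ch4_c_series=ch4,
        growth_series=growth,
        cf_growth_series=cf_growth,
        harvest_base_storage=h_base,
        cf_base_storage=cf_base,
    )


def annual_atmosphere_delta(trajectory: Trajectory) -> np.ndarray:
    """Annual atmospheric change (tC ha^-1 yr^-1, positive = emission).

    Recomputed as the first differences of the storage-gap series between
    the counterfactual and harvest paths; the cumulative sum of the
    result therefore equals the final storage gap.
    """
    return np.diff(trajectory.storage_gap, prepend=0.0)


def delta_co2e_series(trajectory: Trajectory, methane: LandfillParams) -> np.ndarray:
    """Annual series in t CO2e ha^-1 with landfill methane GWP-weighted.

    Carbon fluxes convert at 44/12; the methane-carbon release each year
    carries the extra ``(16/12) * GWP100 - 44/12`` weight on top of its
    storage-change contribution.
    """
    extra = CH4_PER_C * methane.gwp100_ch4 - CO2_PER_C
    return trajectory.delta_series * CO2_PER_C + trajectory.ch4_c_series * extra
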