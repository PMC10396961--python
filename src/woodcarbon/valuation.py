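"""Time discounting of carbon fluxes and substitution benefits.

A wood harvest causes a stream of emissions and removals over the
following decades.  Discounting that stream back to the harvest year
expresses it as a single "harvest-year equivalent" emission:

    PDV_h = sum_{t=0}^{N} dC_t / (1 + d)**t

where ``dC_t`` is the atmospheric change in year ``t`` after the harvest
(positive = emission), ``d`` the discount rate (default 4 %/yr) and
``N`` the valuation horizon (default 40 years, 100 supported).  With
``d = 0`` the PDV is simply the physical change in stored carbon at the
horizon.  National totals multiply the per-hectare PDV of each forest
type by the area of that type newly harvested each year and sum over
harvest years.

Substitution benefits — avoided fossil/process emissions when wood
replaces concrete and steel in construction (1.2 tC saved per tC of
wood) or propane as fuel (0.175 tC per tC) — are always reported
separately from the biogenic carbon costs; they do not change absolute
emissions from harvest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .products import CO2_PER_C

__all__ = [
    "DiscountSpec",
    "HarvestLedger",
    "SubstitutionFactors",
    "pdv",
    "aggregate_pdv",
    "annualize",
    "substitution_benefit",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Discount rate ``d`` (yr^-1) and valuation horizon ``N`` (yr)."""

    d: float = 0.04
    N: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 0.10:
            raise ValueError(f"discount rate d={self.d} outside [0, 0.10]")
        if not 1 <= self.N <= 200:
            raise ValueError(f"horizon N={self.N} outside [1, 200]")


def pdv(deltas: Sequence[float] | np.ndarray, spec: DiscountSpec) -> float:
    """Harvest-year-equivalent value of an annual carbon-change series.

    ``deltas[0]`` is the harvest year.  The series is truncated or
    zero-padded to ``N + 1`` terms; at ``d = 0`` this is the plain sum,
    i.e. the net storage change at the horizon.
    """
    arr = np.asarray(deltas, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("deltas must be a non-empty 1-D series")
    n = spec.N + 1
    arr = arr[:n]
    t = np.arange(arr.size)
    return float(np.sum(arr / (1.0 + spec.d) ** t))


@dataclass
class HarvestLedger:
    """Per-harvest-year per-hectare PDVs and newly harvested areas.

    Year ``start_year + i`` has per-hectare PDVs ``pdv_secondary[i]`` /
    ``pdv_plantation[i]`` (tC ha^-1) and newly harvested areas
    ``area_secondary[i]`` / ``area_plantation[i]`` (ha).
    """

    pdv_secondary: np.ndarray
    pdv_plantation: np.ndarray
    area_secondary: np.ndarray
    area_plantation: np.ndarray
    start_year: int = 2010

    def __post_init__(self) -> None:
        self.pdv_secondary = np.asarray(self.pdv_secondary, dtype=float)
        self.pdv_plantation = np.asarray(self.pdv_plantation, dtype=float)
        self.area_secondary = np.asarray(self.area_secondary, dtype=float)
        self.area_plantation = np.asarray(self.area_plantation, dtype=float)
        k = self.pdv_secondary.size
        for name in ("pdv_plantation", "area_secondary", "area_plantation"):
            if getattr(self, name).size != k:
                raise ValueError(f"ledger column {name} has mismatched length")
        if np.any(self.area_secondary < 0) or np.any(self.area_plantation < 0):
            raise ValueError("harvested areas must be non-negative")

    @property
    def n_years(self) -> int:
        return self.pdv_secondary.size


def aggregate_pdv(ledger: HarvestLedger) -> float:
    """Total discounted carbon cost (tC) over all harvest years.

    Double sum over harvest years and the two forest types of
    per-hectare PDV times newly harvested area.
    """
    return float(
        np.sum(ledger.pdv_secondary * ledger.area_secondary)
        + np.sum(ledger.pdv_plantation * ledger.area_plantation)
    )


def annualize(pdv_total: float, years: float) -> float:
    """Average annual cost in Gt CO2e yr^-1 of a total PDV in tC."""
    if years <= 0:
        raise ValueError(f"years must be positive, got {years}")
    return pdv_total * CO2_PER_C / years / 1e9


@dataclass(frozen=True)
class SubstitutionFactors:
    """Avoided production emissions per tonne of wood carbon used.

    ``construction``: tC saved per tC of wood replacing concrete/steel
    (mid-range literature value 1.2); ``wood_fuel``: tC saved per tC of
    fuelwood replacing propane (0.175); ``construction_share``: share of
    long-lived wood that actually goes into construction.
    """

    construction: float = 1.2
    wood_fuel: float = 0.175
    construction_share: float = 1.0

    def __post_init__(self) -> None:
        if self.construction < 0 or self.wood_fuel < 0:
            raise ValueError("substitution factors must be non-negative")
        if not 0.0 <= self.construction_share <= 1.0:
            raise ValueError(
                f"construction_share={self.construction_share} outside [0, 1]"
            )


def substitution_benefit(
    wood_carbon_by_use: Mapping[str, float], factors: SubstitutionFactors
) -> float:
    """Avoided production emissions (tC) from wood use.

    ``wood_carbon_by_use`` maps ``"llp"`` (long-lived product carbon, of
    which ``construction_share`` substitutes for concrete and steel) and
    ``"vslp_wfl"`` (fuelwood carbon) to tC.  Reported separately from
    biogenic carbon costs, never netted against them.
    """
    for name, v in wood_carbon_by_use.items():
        if v < 0:
            raise ValueError(f"wood carbon for {name!r} is negative ({v})")
    llp = wood_carbon_by_use.get("llp", 0.0)
    wfl = wood_carbon_by_use.get("vslp_wfl", 0.0)
    return llp * factors.construction_share * factors.construction + wfl * factors.wood_fuel
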