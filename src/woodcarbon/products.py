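"""Wood products: volume/carbon conversion, harvest requirements, landfill chain.

Consumption is tracked in four categories, all in cubic metres roundwood
equivalent (RWE, raw-log density):

* ``llp``      — long-lived products: sawn wood, panels, other industrial
                 roundwood (construction and furniture);
* ``slp``      — short-lived products: paper and paperboard;
* ``vslp_wfl`` — wood harvested deliberately for fuel;
* ``vslp_ind`` — manufacturing wastes of the other products burned for
                 energy.

Consuming one unit of a processed product requires more than one unit of
roundwood harvest (sawmill and pulping losses); paper demand is first
reduced to its virgin-pulp share (the remainder comes from recovered
paper), and industrial-waste fuel demand is satisfied from the co-product
waste stream of other products before any additional harvest is booked.

Decayed long-lived products enter landfills, where released carbon splits
between CO2 and methane; methane is weighted by its 100-year global
warming potential when expressed as CO2e.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

PRODUCTS = ("llp", "slp", "vslp_wfl", "vslp_ind")

#: kg CO2 per kg C and kg CH4 per kg C
CO2_PER_C = 44.0 / 12.0
CH4_PER_C = 16.0 / 12.0

__all__ = [
    "PRODUCTS",
    "CO2_PER_C",
    "CH4_PER_C",
    "ProductShares",
    "ConversionTable",
    "LandfillParams",
    "LandfillRelease",
    "volume_to_carbon",
    "carbon_to_volume",
    "roundwood_from_consumption",
    "landfill_step",
]


@dataclass(frozen=True)
class ProductShares:
    """Fractions of harvested carbon allocated to each product category."""

    llp: float
    slp: float
    vslp_wfl: float
    vslp_ind: float

    def __post_init__(self) -> None:
        for name in PRODUCTS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"product share {name}={v} outside [0, 1]")
        total = self.llp + self.slp + self.vslp_wfl + self.vslp_ind
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"product shares sum to {total!r}, expected 1")

    @property
    def vslp(self) -> float:
        """Total very-short-lived share (burned in the harvest year)."""
        return self.vslp_wfl + self.vslp_ind

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PRODUCTS}


def _default_ratios() -> dict[str, float]:
    # m3 roundwood harvested per m3 RWE of product consumed; >1 encodes
    # processing losses. Fuelwood is used as harvested.
    return {"llp": 2.0, "slp": 2.4, "vslp_wfl": 1.0, "vslp_ind": 1.0}


@dataclass(frozen=True)
class ConversionTable:
    """Volume/carbon conversion factors and roundwood-per-product ratios.

    Parameters
    ----------
    wood_density : float
        Tonnes dry matter per m3 of roundwood (0.48 for raw harvests).
    carbon_fraction : float
        Carbon content of dry matter (dimensionless).
    pulp_share_virgin : float
        Share of paper production supplied by virgin wood pulp (0.40);
        the remainder comes from recovered paper and other pulp and
        requires no new harvest.
    ratios : mapping
        m3 roundwood per m3 RWE consumed, by product category.
    waste_burn_share : float
        Share of processing waste available to satisfy industrial-waste
        fuel (``vslp_ind``) demand.
    """

    wood_density: float = 0.48
    carbon_fraction: float = 0.5
    pulp_share_virgin: float = 0.40
    ratios: Mapping[str, float] = field(default_factory=_default_ratios)
    waste_burn_share: float = 1.0

    def __post_init__(self) -> None:
        if self.wood_density <= 0:
            raise ValueError(f"wood_density must be positive, got {self.wood_density}")
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError(
                f"carbon_fraction must be in (0, 1), got {self.carbon_fraction}"
            )
        if not 0.0 <= self.pulp_share_virgin <= 1.0:
            raise ValueError(
                f"pulp_share_virgin must be in [0, 1], got {self.pulp_share_virgin}"
            )
        if not 0.0 <= self.waste_burn_share <= 1.0:
            raise ValueError(
                f"waste_burn_share must be in [0, 1], got {self.waste_burn_share}"
            )
        for name, r in self.ratios.items():
            if r < 1.0:
                raise ValueError(
                    f"roundwood ratio for {name} is {r}; ratios are >= 1 "
                    "(processing cannot create wood)"
                )

    @property
    def carbon_per_m3(self) -> float:
        """tC per m3 roundwood equivalent."""
        return self.wood_density * self.carbon_fraction


def volume_to_carbon(volume: float, table: ConversionTable) -> float:
    """Carbon content (tC) of ``volume`` m3 roundwood equivalent."""
    if volume < 0:
        raise ValueError(f"volume must be non-negative, got {volume}")
    return volume * table.carbon_per_m3


def carbon_to_volume(carbon: float, table: ConversionTable) -> float:
    """Roundwood-equivalent volume (m3) holding ``carbon`` tC."""
    if carbon < 0:
        raise ValueError(f"carbon must be non-negative, got {carbon}")
    return carbon / table.carbon_per_m3


def roundwood_from_consumption(
    consumption: Mapping[str, float], table: ConversionTable
) -> dict[str, float]:
    """Roundwood harvest (m3) required to meet product consumption.

    Applies per-product roundwood ratios; paper demand is reduced to its
    virgin-pulp share before the pulping ratio; industrial-waste fuel
    demand is met from co-product processing waste first, with only the
    shortfall booked as additional harvest.

    Returns a dict keyed by product category plus ``"total"``.  Entries
    are the *new harvest* attributable to each category.
    """
    for name, v in consumption.items():
        if v < 0:
            raise ValueError(f"consumption for {name} is negative ({v})")
        if name not in PRODUCTS:
            raise KeyError(f"unknown product category {name!r}")
    missing = [p for p in consumption if p not in table.ratios]
    if missing:
        raise KeyError(f"no roundwood ratio configured for: {missing}")

    c_llp = consumption.get("llp", 0.0)
    c_slp = consumption.get("slp", 0.0)
    c_wfl = consumption.get("vslp_wfl", 0.0)
    c_ind = consumption.get("vslp_ind", 0.0)

    h_llp = c_llp * table.ratios["llp"]
    virgin_paper = c_slp * table.pulp_share_virgin
    h_slp = virgin_paper * table.ratios["slp"]
    h_wfl = c_wfl * table.ratios["vslp_wfl"]

    waste = (h_llp - c_llp) + (h_slp - virgin_paper)
    available_waste = waste * table.waste_burn_share
    h_ind = max(0.0, c_ind - available_waste) * table.ratios["vslp_ind"]

    out = {"llp": h_llp, "slp": h_slp, "vslp_wfl": h_wfl, "vslp_ind": h_ind}
    out["total"] = h_llp + h_slp + h_wfl + h_ind
    return out


@dataclass(frozen=True)
class LandfillParams:
    """Fate of carbon leaving the long-lived-product pool.

    ``landfill_fraction_of_llp_decay`` of decayed LLP carbon enters the
    landfill pool (the rest is burned or oxidizes as CO2).  Of carbon the
    landfill releases, ``methane_fraction`` leaves as CH4-C and the rest
    as CO2-C; CH4 is weighted by ``gwp100_ch4`` in CO2e.
    """

    landfill_fraction_of_llp_decay: float = 0.5
    methane_fraction: float = 0.2
    gwp100_ch4: float = 28.0

    def __post_init__(self) -> None:
        for name in ("landfill_fraction_of_llp_decay", "methane_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gwp100_ch4 <= 1.0:
            raise ValueError(
                f"gwp100_ch4 must exceed 1 (CH4 warms more than CO2), "
                f"got {self.gwp100_ch4}"
            )


class LandfillRelease(NamedTuple):
    remaining: float  # tC still stored
    co2_c: float      # tC released as CO2
    ch4_c: float      # tC released as CH4
    co2e: float       # t CO2e of the release (GWP100-weighted)


def landfill_step(stock: float, params: LandfillParams, half_life: float) -> LandfillRelease:
    """One annual decay step of the landfill pool.

    Carbon is conserved: ``remaining + co2_c + ch4_c == stock``.  The
    CO2e of the release is ``co2_c*44/12 + ch4_c*(16/12)*GWP100``, so it
    is never below ``44/12`` times the released carbon and equals it only
    when no methane forms.
    """
    from .stand import decay_step  # local import to avoid a cycle

    remaining, released = decay_step(stock, half_life)
    ch4_c = released * params.methane_fraction
    co2_c = released - ch4_c
    co2e = co2_c * CO2_PER_C + ch4_c * CH4_PER_C * params.gwp100_ch4
    return LandfillRelease(remaining, co2_c, ch4_c, co2e)
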