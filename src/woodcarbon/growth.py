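"""Forest growth curves.

National inventories typically report forest growth as mean annual
above-ground carbon increments in two broad age bands (young stands,
below ~20 years, and older stands).  Year-by-year carbon bookkeeping
needs a continuous accumulation curve, so the two band rates are
converted into a Monod (saturating hyperbola) curve

    AGB(age) = a_max * age / (k_half + age)

which is a reasonable proxy for stand-level biomass accumulation:
increments are largest in young stands and decline monotonically as
biomass approaches the asymptote ``a_max``.

Below-ground biomass follows the widely used allometric power law
``BGB = c * AGB**p`` relating root to shoot biomass.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GrowthBands",
    "MonodCurve",
    "RootShootParams",
    "MonodFitError",
    "agb_at_age",
    "fit_monod",
    "band_rates",
    "bgb_from_agb",
]


class MonodFitError(ValueError):
    """Raised when band increments admit no Monod curve (young <= old)."""


@dataclass(frozen=True)
class GrowthBands:
    """Mean annual above-ground carbon increments in two age bands.

    Parameters
    ----------
    young_rate : float
        Mean annual increment for stand ages in ``(0, band_width]``,
        tC ha^-1 yr^-1.
    old_rate : float
        Mean annual increment for ages in ``(band_width, 2*band_width]``,
        tC ha^-1 yr^-1.
    band_width : int
        Years per band (20 in standard inventory tables).
    """

    young_rate: float
    old_rate: float
    band_width: float = 20.0

    def __post_init__(self) -> None:
        if self.young_rate <= 0 or self.old_rate <= 0:
            raise ValueError(
                f"band rates must be positive, got young={self.young_rate}, "
                f"old={self.old_rate}"
            )
        if self.band_width <= 0:
            raise ValueError(f"band_width must be positive, got {self.band_width}")


@dataclass(frozen=True)
class MonodCurve:
    """Saturating biomass-accumulation curve AGB(age) = a_max*age/(k_half+age).

    ``a_max`` is the asymptotic above-ground biomass (tC ha^-1) and
    ``k_half`` the age (yr) at which half of it is reached.
    """

    a_max: float
    k_half: float

    def __post_init__(self) -> None:
        if self.a_max <= 0:
            raise ValueError(f"a_max must be positive, got {self.a_max}")
        if self.k_half <= 0:
            raise ValueError(f"k_half must be positive, got {self.k_half}")

    def agb(self, age: float) -> float:
        """Above-ground biomass (tC ha^-1) at ``age`` years."""
        return agb_at_age(self, age)


@dataclass(frozen=True)
class RootShootParams:
    """Power-law root:shoot allometry BGB = coefficient * AGB**exponent.

    Defaults follow the widely used cross-biome fit (0.489, 0.89).
    """

    coefficient: float = 0.489
    exponent: float = 0.89

    def __post_init__(self) -> None:
        if self.coefficient <= 0 or self.exponent <= 0:
            raise ValueError(
                f"root:shoot parameters must be positive, got "
                f"coefficient={self.coefficient}, exponent={self.exponent}"
            )

    def bgb(self, agb: float) -> float:
        """Below-ground biomass (tC ha^-1) for a stand with ``agb``."""
        return bgb_from_agb(self, agb)


def agb_at_age(curve: MonodCurve, age: float) -> float:
    """Above-ground biomass (tC ha^-1) of a stand of ``age`` years.

    Monotone increasing, concave, zero at age 0 and bounded by
    ``curve.a_max``.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return curve.a_max * age / (curve.k_half + age)


def band_rates(curve: MonodCurve, band_width: float = 20.0) -> GrowthBands:
    """Mean annual increments of ``curve`` over the two inventory bands.

    Inverse of :func:`fit_monod`: the young rate is AGB(b)/b and the old
    rate (AGB(2b) - AGB(b))/b for band width b.
    """
    b = band_width
    young = agb_at_age(curve, b) / b
    old = (agb_at_age(curve, 2 * b) - agb_at_age(curve, b)) / b
    return GrowthBands(young_rate=young, old_rate=old, band_width=b)


def fit_monod(bands: GrowthBands) -> MonodCurve:
    """Fit a Monod curve whose band-mean increments match ``bands`` exactly.

    Matching the mean annual increment over ``(0, b]`` and ``(b, 2b]``
    gives two equations in (a_max, k_half) with the closed-form solution

        k_half = 2 b m_old / (m_young - m_old)
        a_max  = m_young (k_half + b)

    Raises
    ------
    MonodFitError
        If ``young_rate <= old_rate``: Monod increments strictly decline,
        so non-declining band rates admit no fit.
    """
    m1, m2, b = bands.young_rate, bands.old_rate, bands.band_width
    if m1 <= m2:
        raise MonodFitError(
            f"no Monod curve matches non-declining band rates "
            f"(young={m1}, old={m2}); increments must decline with age"
        )
    k_half = 2.0 * b * m2 / (m1 - m2)
    a_max = m1 * (k_half + b)
    return MonodCurve(a_max=a_max, k_half=k_half)


def bgb_from_agb(params: RootShootParams, agb: float) -> float:
    """Below-ground biomass (tC ha^-1) from above-ground biomass."""
    if agb < 0:
        raise ValueError(f"agb must be non-negative, got {agb}")
    if agb == 0:
        return 0.0
    return params.coefficient * agb**params.exponent
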