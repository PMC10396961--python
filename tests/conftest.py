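import numpy as np
import pytest

from woodcarbon.growth import MonodCurve, RootShootParams
from woodcarbon.products import LandfillParams, ProductShares
from woodcarbon.stand import HalfLives, StandParams
from woodcarbon.synthdata import SynthSpec, build_world


@pytest.fixture
def simple_curve() -> MonodCurve:
    """Half-saturation at 20 yr, asymptote 200 tC/ha: AGB(20) = 100."""
    return MonodCurve(a_max=200.0, k_half=20.0)


@pytest.fixture
def linear_roots() -> RootShootParams:
    """Linear root:shoot (exponent 1) keeps hand arithmetic simple."""
    return RootShootParams(coefficient=0.25, exponent=1.0)


@pytest.fixture
def basic_params(simple_curve, linear_roots) -> StandParams:
    return StandParams(
        curve=simple_curve,
        rootshoot=linear_roots,
        slash_fraction=0.3,
        product_shares=ProductShares(llp=0.5, slp=0.25, vslp_wfl=0.25, vslp_ind=0.0),
        half_lives=HalfLives(slash=10.0, roots=10.0, llp=35.0, slp=2.0, landfill=29.0),
        methane=LandfillParams(),
    )


@pytest.fixture(scope="session")
def small_world():
    """Fixed 10-country synthetic world with projected 2050 demand."""
    return build_world(SynthSpec(seed=0, n_countries=10))


def random_stand_params(rng: np.random.Generator) -> tuple[StandParams, float, float]:
    """Random but valid stand parameters: (params, efficiency, harvest age)."""
    shares = rng.dirichlet(np.ones(4))
    curve = MonodCurve(a_max=rng.uniform(50, 400), k_half=rng.uniform(5, 60))
    params = StandParams(
        curve=curve,
        rootshoot=RootShootParams(rng.uniform(0.1, 0.6), rng.uniform(0.7, 1.0)),
        slash_fraction=rng.uniform(0.0, 1.0),
        product_shares=ProductShares(*shares),
        half_lives=HalfLives(*rng.uniform(0.5, 60, size=5)),
        rotation=int(rng.integers(5, 40)),
        methane=LandfillParams(
            landfill_fraction_of_llp_decay=rng.uniform(0, 1),
            methane_fraction=rng.uniform(0, 1),
            gwp100_ch4=rng.uniform(20, 40),
        ),
    )
    return params, float(rng.uniform(0.2, 1.0)), float(rng.uniform(10, 80))
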