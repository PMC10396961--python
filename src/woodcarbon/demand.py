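"""National wood-demand projection with a log-transformed fixed-effects model.

Historical consumption of each wood-product category is regressed,
within countries, on log population, log GDP per capita and optionally a
time trend (years after 2000, a proxy for technology and policy change):

    log C_it = alpha_i + b_pop log P_it + b_gdp log g_it [+ b_t (year-2000)] + e_it

Countries are split into developed and developing groups so that
saturation of wood use in rich countries does not inflate projections
elsewhere.  Three product categories (long-lived, short-lived, fuelwood)
times two groups times two formulae give twelve model variants.

Projection to 2050 applies the fitted elasticities to exogenous
population and GDP-per-capita growth factors, anchored to each country's
own 2010 consumption (an average of 2006-2014 in the data pipeline);
demand between 2010 and 2050 is interpolated linearly.  Trade is frozen
at base-year structure: each country keeps its net-import share of
consumption, and exporters supply global imports in fixed proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

REGRESSION_PRODUCTS = ("llp", "slp", "vslp_wfl")

__all__ = [
    "REGRESSION_PRODUCTS",
    "FEModel",
    "fit_fe_model",
    "fit_all_models",
    "project_consumption",
    "interpolate_demand",
    "apply_trade",
]


@dataclass
class FEModel:
    """Fitted coefficients of one fixed-effects demand regression."""

    product: str
    group: str                     # "developed" | "developing"
    with_time: bool
    beta_pop: float
    beta_gdp_pc: float
    beta_time: float | None
    country_intercepts: dict[str, float]
    r_squared: float
    resid_se: float
    nobs: int
    beta_pop_se: float = float("nan")
    beta_gdp_pc_se: float = float("nan")


def _prepare(panel: pd.DataFrame, product: str, group: str) -> pd.DataFrame:
    required = {"country", "year", "product", "consumption", "gdp_pc", "population", "developed"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    want_developed = {"developed": True, "developing": False}[group]
    sub = panel[(panel["product"] == product) & (panel["developed"] == want_developed)]
    # zero or missing consumption-years cannot be log-transformed; drop them
    sub = sub[(sub["consumption"] > 0) & sub["consumption"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no usable rows for product={product!r}, group={group!r}")
    sub["log_c"] = np.log(sub["consumption"].astype(float))
    sub["log_pop"] = np.log(sub["population"].astype(float))
    sub["log_gdp"] = np.log(sub["gdp_pc"].astype(float))
    sub["t2000"] = sub["year"].astype(float) - 2000.0
    return sub


def fit_fe_model(
    panel: pd.DataFrame, product: str, group: str, with_time: bool
) -> FEModel:
    """Fit one of the twelve demand-model variants by within-country OLS.

    ``panel`` is long-format with columns country, year, product,
    consumption (m3 RWE), gdp_pc, population and a boolean ``developed``.
    Country fixed effects are estimated as dummy intercepts.
    """
    sub = _prepare(panel, product, group)
    n_countries = sub["country"].nunique()
    counts = sub.groupby("country")["year"].nunique()
    if n_countries >= 2 and (counts < 3).any():
        few = counts[counts < 3].index.tolist()
        raise ValueError(f"countries with fewer than 3 usable years: {few}")

    rhs = "np.log(population) + np.log(gdp_pc)"
    if with_time:
        rhs += " + t2000"
    if n_countries >= 2:
        formula = f"log_c ~ {rhs} + C(country)"
    else:
        # a single country's fixed effect is just the intercept
        formula = f"log_c ~ {rhs}"
    res = smf.ols(formula, data=sub).fit()

    params = res.params
    intercept = float(params["Intercept"])
    intercepts: dict[str, float] = {}
    countries = sorted(sub["country"].unique())
    for c in countries:
        key = f"C(country)[T.{c}]"
        intercepts[c] = intercept + (float(params[key]) if key in params else 0.0)

    return FEModel(
        product=product,
        group=group,
        with_time=with_time,
        beta_pop=float(params["np.log(population)"]),
        beta_gdp_pc=float(params["np.log(gdp_pc)"]),
        beta_time=float(params["t2000"]) if with_time else None,
        country_intercepts=intercepts,
        r_squared=float(res.rsquared),
        resid_se=float(np.sqrt(res.mse_resid)),
        nobs=int(res.nobs),
        beta_pop_se=float(res.bse["np.log(population)"]),
        beta_gdp_pc_se=float(res.bse["np.log(gdp_pc)"]),
    )


def fit_all_models(panel: pd.DataFrame) -> dict[tuple[str, str, bool], FEModel]:
    """Fit all 12 variants (3 products x 2 groups x with/without time)."""
    out: dict[tuple[str, str, bool], FEModel] = {}
    for product in REGRESSION_PRODUCTS:
        for group in ("developed", "developing"):
            for with_time in (False, True):
                out[(product, group, with_time)] = fit_fe_model(
                    panel, product, group, with_time
                )
    return out


def project_consumption(
    model: FEModel,
    base: float,
    pop_factor: float,
    gdp_factor: float,
    years_ahead: float = 40.0,
) -> float:
    """Project 2050 consumption from a 2010 base (m3 RWE).

    Applies the fitted elasticities to growth *factors* (2050/2010
    ratios) of population and GDP per capita, anchored to the country's
    own base-year consumption; the time trend, when fitted, contributes
    ``exp(beta_time * years_ahead)``.
    """
    if base <= 0:
        raise ValueError(f"base consumption must be positive, got {base}")
    if pop_factor <= 0 or gdp_factor <= 0:
        raise ValueError("growth factors must be positive")
    out = base * pop_factor**model.beta_pop * gdp_factor**model.beta_gdp_pc
    if model.with_time and model.beta_time is not None:
        out *= math.exp(model.beta_time * years_ahead)
    return out


def interpolate_demand(
    c2010: float, c2050: float, start_year: int = 2010, end_year: int = 2050
) -> pd.Series:
    """Linear annual consumption series between the two endpoint years."""
    if c2010 < 0 or c2050 < 0:
        raise ValueError("consumption endpoints must be non-negative")
    years = np.arange(start_year, end_year + 1)
    frac = (years - start_year) / (end_year - start_year)
    return pd.Series(c2010 + frac * (c2050 - c2010), index=years)


def apply_trade(
    consumption: pd.Series,
    net_import_share: Mapping[str, float],
    export_share: Mapping[str, float],
) -> pd.Series:
    """Convert national consumption to national production, trade frozen.

    ``net_import_share[c]`` is the base-year share of country ``c``'s
    consumption supplied by net imports (0 for net exporters);
    ``export_share[c]`` is its base-year share of aggregate global
    exports (summing to 1 when any country imports).  Production equals
    consumption minus imports plus the country's share of global
    exports, so global production equals global consumption exactly.
    """
    cons = consumption.astype(float)
    mis = pd.Series({c: net_import_share.get(c, 0.0) for c in cons.index}, dtype=float)
    exs = pd.Series({c: export_share.get(c, 0.0) for c in cons.index}, dtype=float)
    if (mis < 0).any() or (mis > 1).any():
        bad = mis[(mis < 0) | (mis > 1)].index.tolist()
        raise ValueError(f"net import shares outside [0, 1] for: {bad}")
    total_imports = float((cons * mis).sum())
    if total_imports > 0:
        es_sum = float(exs.sum())
        if es_sum <= 0:
            raise ValueError("imports demanded but no export shares configured")
        exs = exs / es_sum
    production = cons - cons * mis + exs * total_imports
    return production
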