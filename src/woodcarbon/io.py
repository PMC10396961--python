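"""Configuration, tabular readers/writers and result serialization.

All inputs are local files: CSV tables (UTF-8, header row, '.' decimal)
plus one declarative YAML run configuration.  Loaders validate schemas
up front and raise :class:`SchemaError` naming the file, column and row
of the first violation, before any computation starts.  Writers are
atomic (write to a temporary file, then rename) so a failed run never
leaves truncated outputs, and every run emits a JSON manifest from which
it can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthBands, MonodCurve, RootShootParams, fit_monod
from .products import PRODUCTS, ConversionTable, LandfillParams
from .stand import HalfLives
from .supply import CountryProfile, ScenarioResult, WorldInputs
from .valuation import DiscountSpec, SubstitutionFactors

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_config",
    "load_tables",
    "read_profiles",
    "write_profiles",
    "read_demand",
    "write_demand",
    "read_panel",
    "write_panel",
    "read_growth_factors",
    "write_growth_factors",
    "read_product_shares",
    "write_results",
]


class SchemaError(ValueError):
    """Input-table validation failure, naming file, column and row."""

    def __init__(self, file: str | Path, message: str, column: str | None = None,
                 row: Any | None = None):
        self.file = str(file)
        self.column = column
        self.row = row
        loc = self.file
        if column is not None:
            loc += f", column {column!r}"
        if row is not None:
            loc += f", row {row!r}"
        super().__init__(f"{loc}: {message}")


PROFILE_COLUMNS = [
    "country", "tropical", "plantation_area_2010",
    "plantation_young_rate", "plantation_old_rate",
    "secondary_young_rate", "secondary_old_rate",
    "plantation_rotation", "secondary_age_at_harvest",
    "harvest_efficiency", "slash_fraction_secondary", "slash_fraction_plantation",
    "net_import_share", "export_share", "construction_share",
    "root_shoot_coef", "root_shoot_exp",
]

PANEL_COLUMNS = ["country", "year", "product", "consumption", "gdp_pc", "population", "developed"]


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(path, f"missing required columns {missing}")


def read_profiles(path: str | Path) -> dict[str, CountryProfile]:
    """Load country supply profiles from CSV, fitting growth curves."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, path)
    profiles: dict[str, CountryProfile] = {}
    for idx, row in df.iterrows():
        country = str(row["country"])
        for col in ("plantation_young_rate", "secondary_young_rate"):
            old_col = col.replace("young", "old")
            if row[col] <= row[old_col]:
                raise SchemaError(
                    path, "young-band growth rate must exceed old-band rate "
                    f"({row[col]} <= {row[old_col]})", column=col, row=country,
                )
        for col, lo, hi in (
            ("harvest_efficiency", 0.0, 1.0),
            ("net_import_share", 0.0, 1.0),
            ("construction_share", 0.0, 1.0),
            ("slash_fraction_secondary", 0.0, 1.0),
            ("slash_fraction_plantation", 0.0, 1.0),
        ):
            if not lo <= row[col] <= hi:
                raise SchemaError(
                    path, f"value {row[col]} outside [{lo}, {hi}]",
                    column=col, row=country,
                )
        try:
            profiles[country] = CountryProfile(
                name=country,
                tropical=bool(row["tropical"]),
                plantation_area_2010=float(row["plantation_area_2010"]),
                plantation_curve=fit_monod(
                    GrowthBands(row["plantation_young_rate"], row["plantation_old_rate"])
                ),
                secondary_curve=fit_monod(
                    GrowthBands(row["secondary_young_rate"], row["secondary_old_rate"])
                ),
                plantation_rotation=int(row["plantation_rotation"]),
                secondary_age_at_harvest=float(row["secondary_age_at_harvest"]),
                harvest_efficiency=float(row["harvest_efficiency"]),
                slash_fraction_secondary=float(row["slash_fraction_secondary"]),
                slash_fraction_plantation=float(row["slash_fraction_plantation"]),
                net_import_share=float(row["net_import_share"]),
                export_share=float(row["export_share"]),
                construction_share=float(row["construction_share"]),
                rootshoot=RootShootParams(
                    float(row["root_shoot_coef"]), float(row["root_shoot_exp"])
                ),
            )
        except ValueError as exc:
            raise SchemaError(path, str(exc), row=country) from exc
    if not profiles:
        raise SchemaError(path, "no country rows")
    return profiles


def write_profiles(profiles: Mapping[str, CountryProfile], path: str | Path) -> None:
    from .growth import band_rates

    rows = []
    for p in profiles.values():
        pb = band_rates(p.plantation_curve)
        sb = band_rates(p.secondary_curve)
        rows.append(
            {
                "country": p.name,
                "tropical": p.tropical,
                "plantation_area_2010": p.plantation_area_2010,
                "plantation_young_rate": pb.young_rate,
                "plantation_old_rate": pb.old_rate,
                "secondary_young_rate": sb.young_rate,
                "secondary_old_rate": sb.old_rate,
                "plantation_rotation": p.plantation_rotation,
                "secondary_age_at_harvest": p.secondary_age_at_harvest,
                "harvest_efficiency": p.harvest_efficiency,
                "slash_fraction_secondary": p.slash_fraction_secondary,
                "slash_fraction_plantation": p.slash_fraction_plantation,
                "net_import_share": p.net_import_share,
                "export_share": p.export_share,
                "construction_share": p.construction_share,
                "root_shoot_coef": p.rootshoot.coefficient,
                "root_shoot_exp": p.rootshoot.exponent,
            }
        )
    _atomic_to_csv(pd.DataFrame(rows), Path(path))


def read_demand(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load 2010/2050 consumption (long CSV) into two country x product frames."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["country", "product", "consumption_2010", "consumption_2050"], path)
    bad = df[~df["product"].isin(PRODUCTS)]
    if not bad.empty:
        raise SchemaError(
            path, f"unknown product {bad.iloc[0]['product']!r}",
            column="product", row=int(bad.index[0]),
        )
    for col in ("consumption_2010", "consumption_2050"):
        neg = df[df[col] < 0]
        if not neg.empty:
            raise SchemaError(
                path, f"negative consumption {neg.iloc[0][col]}",
                column=col, row=int(neg.index[0]),
            )
    d2010 = df.pivot(index="country", columns="product", values="consumption_2010")
    d2050 = df.pivot(index="country", columns="product", values="consumption_2050")
    for name, d in (("consumption_2010", d2010), ("consumption_2050", d2050)):
        if d.isna().any().any():
            raise SchemaError(path, f"missing {name} entries for some country-product pairs")
    return d2010[list(PRODUCTS)], d2050[list(PRODUCTS)]


def write_demand(d2010: pd.DataFrame, d2050: pd.DataFrame, path: str | Path) -> None:
    long = (
        d2010.stack().rename("consumption_2010").to_frame()
        .join(d2050.stack().rename("consumption_2050"))
        .reset_index()
    )
    long.columns = ["country", "product", "consumption_2010", "consumption_2050"]
    _atomic_to_csv(long, Path(path))


def read_panel(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, path)
    neg = df[(df["population"] <= 0) | (df["gdp_pc"] <= 0)]
    if not neg.empty:
        raise SchemaError(
            path, "population and gdp_pc must be positive",
            column="population", row=int(neg.index[0]),
        )
    df["developed"] = df["developed"].astype(bool)
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    _atomic_to_csv(panel[PANEL_COLUMNS], Path(path))


def read_growth_factors(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["country", "pop_factor", "gdp_factor"], path)
    bad = df[(df["pop_factor"] <= 0) | (df["gdp_factor"] <= 0)]
    if not bad.empty:
        raise SchemaError(
            path, "growth factors must be positive",
            column="pop_factor", row=int(bad.index[0]),
        )
    return df.set_index("country")


def write_growth_factors(factors: pd.DataFrame, path: str | Path) -> None:
    _atomic_to_csv(factors.reset_index(), Path(path))


def read_product_shares(path: str | Path) -> pd.DataFrame:
    """Optional per-country product-share table; rows must sum to 1."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["country", *PRODUCTS], path)
    sums = df[list(PRODUCTS)].sum(axis=1)
    bad = df[(sums - 1.0).abs() > 1e-6]
    if not bad.empty:
        raise SchemaError(
            path, f"product shares sum to {sums[bad.index[0]]:.6g}, expected 1",
            column="llp..vslp_ind", row=str(bad.iloc[0]["country"]),
        )
    return df.set_index("country")


@dataclass
class RunConfig:
    """Declarative run configuration (usually parsed from YAML)."""

    profiles: Path
    demand: Path
    output_dir: Path
    scenario: int = 1
    discount_rate: float = 0.04
    horizon: int = 40
    seed: int = 0
    start_year: int = 2010
    end_year: int = 2050
    n_harvest_years: int = 40
    coverage: float = 0.8
    high_efficiency: float = 0.8
    half_lives: dict[str, float] = field(default_factory=dict)
    methane: dict[str, float] = field(default_factory=dict)
    conversion: dict[str, float] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("profiles", "demand", "output_dir"):
        if key not in raw:
            raise SchemaError(path, f"missing required config key {key!r}")
    base = path.parent
    cfg = RunConfig(
        profiles=base / raw.pop("profiles"),
        demand=base / raw.pop("demand"),
        output_dir=base / raw.pop("output_dir"),
        **raw,
    )
    if not 1 <= cfg.scenario <= 7:
        raise SchemaError(path, f"scenario must be 1-7, got {cfg.scenario}")
    for name, v in cfg.half_lives.items():
        if v <= 0:
            raise SchemaError(path, f"half-life {name}={v} must be positive",
                              column=f"half_lives.{name}")
    for p in (cfg.profiles, cfg.demand):
        if not p.exists():
            raise SchemaError(path, f"referenced file does not exist: {p}")
    return cfg


def load_tables(config: RunConfig) -> WorldInputs:
    """Read and validate all tables referenced by ``config``."""
    profiles = read_profiles(config.profiles)
    d2010, d2050 = read_demand(config.demand)
    unknown = set(d2010.index) - set(profiles)
    if unknown:
        raise SchemaError(
            config.demand, f"countries without profiles: {sorted(unknown)}",
            column="country",
        )
    return WorldInputs(
        profiles=profiles,
        demand_2010=d2010,
        demand_2050=d2050,
        conversion=ConversionTable(**config.conversion),
        half_lives=HalfLives(**config.half_lives),
        methane=LandfillParams(**config.methane),
        discount=DiscountSpec(d=config.discount_rate, N=config.horizon),
        substitution=SubstitutionFactors(),
        start_year=config.start_year,
        end_year=config.end_year,
        n_harvest_years=config.n_harvest_years,
        coverage=config.coverage,
        high_efficiency=config.high_efficiency,
    )


def _atomic_to_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _atomic_json(obj: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
    os.replace(tmp, path)


def write_results(results: list[ScenarioResult], config: RunConfig | None,
                  output_dir: str | Path) -> dict[str, Path]:
    """Write tidy result CSVs plus a JSON run manifest.

    ``summary.csv`` mirrors the cost decomposition (2010-level vs
    additional demand, substitution reported separately, areas);
    ``per_country.csv`` holds national PDVs and areas.  Files are
    written atomically.
    """
    outdir = Path(output_dir)
    summary_rows = []
    country_frames = []
    for r in results:
        summary_rows.append(
            {
                "scenario": r.scenario.id,
                "scenario_name": r.scenario.name,
                "annualized_cost_gtco2e_yr": r.annualized_cost,
                "cost_2010_demand_gtco2e_yr": r.cost_2010_level,
                "additional_demand_cost_gtco2e_yr": r.additional_cost,
                "substitution_savings_gtco2e_yr": r.substitution_savings,
                "area_total_mha": r.area_total_mha,
                "area_secondary_mha": r.area_secondary_mha,
                "area_plantation_mha": r.area_plantation_mha,
                "pdv_total_tc": r.pdv_total_tc,
            }
        )
        pc = r.per_country.reset_index()
        pc.insert(0, "scenario", r.scenario.id)
        country_frames.append(pc)

    paths = {
        "summary": outdir / "summary.csv",
        "per_country": outdir / "per_country.csv",
        "manifest": outdir / "manifest.json",
    }
    _atomic_to_csv(pd.DataFrame(summary_rows), paths["summary"])
    _atomic_to_csv(pd.concat(country_frames, ignore_index=True), paths["per_country"])

    from . import __version__

    manifest: dict[str, Any] = {"package_version": __version__}
    if config is not None:
        cfg = asdict(config)
        manifest["config"] = {
            k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()
        }
    manifest["scenarios"] = [r.scenario.id for r in results]
    _atomic_json(manifest, paths["manifest"])
    return paths
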