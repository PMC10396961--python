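# Methods

## Model overview

`woodcarbon` is a bookkeeping model of the carbon consequences of wood
harvest.  For every harvested hectare it runs two parallel paths:

* **harvest path** — the stand is clear-cut at the start of the harvest
  year; felled above-ground carbon splits into slash (left on site),
  recovered wood products and an immediate emission (the very-short-
  lived share is burned at once); live roots become dead roots; the
  stand regrows from age zero along a designated curve, and dead and
  product pools decay year by year;
* **counterfactual path** — the same stand keeps growing, unharvested,
  "evolving independently of direct human activity".

The atmospheric effect in year *t* is the first difference of the gap
between stored carbon on the two paths (positive = emission).  The
stream is valued as a harvest-year equivalent: `PDV = Σ ΔC_t/(1+d)^t`
over `N` years.  National and global totals multiply per-hectare PDVs
by the areas newly harvested each year, for plantations and secondary
forests separately, over 40 harvest years (2010–2049), and divide by
40 to annualize.  Totals from the ~30 modelled countries are divided by
their assumed 0.8 share of world production to give global numbers.

## Growth

Inventory tables give mean annual above-ground carbon increments in two
age bands (default width 20 yr).  A Monod curve
`AGB(t) = a_max·t/(k_half+t)` is fitted so that its band-mean increments
match both rates exactly; the two-equation system has the closed form
`k_half = 2b·m_old/(m_young − m_old)`, `a_max = m_young·(k_half + b)`,
which exists iff increments decline (`m_young > m_old`).  The old-band
rate is implicitly extended by the curve beyond age `2b`; biomass is
always capped by `a_max`.  Below-ground biomass uses the power law
`BGB = 0.489·AGB^0.89` by default (cross-biome literature fit); both
parameters are ordinary config values, never hard-coded downstream.

## Stand bookkeeping

Discrete annual steps with these conventions:

* harvest at the start of the year; regrowth of the new stand begins
  the following year (so the first year after harvest ends at age 1);
* pools decay first-order with per-step retention `2^(-1/half_life)`
  — the stock halves after exactly one half-life of annual steps —
  starting the year **after** the pool is created;
* harvest losses (share `1 − efficiency` of removable wood) stay on
  site as slash, alongside the configured slash fraction;
* decayed short-lived products are burned (CO2); a configurable share
  of decayed long-lived products enters landfill; landfill releases
  split into CO2 and CH4, with CH4 weighted by GWP100 when results are
  expressed in CO2e;
* thinnings remove a configured fraction of live biomass to products on
  the same land (no area increment);
* carbon closes exactly: every year, the change in (all pools +
  cumulative emissions) equals new live growth, verified to 1e-9 tC/ha
  in tests.

One consequence of the regeneration-year convention is that a stand
re-harvested after a rotation of `R` calendar years is felled at curve
age `R − 1`; supply bookkeeping uses the rotation-age yield.  The
discrepancy is one year of growth per rotation and is accepted as part
of the discrete timing.

Default half-lives (years): slash 10, dead roots 10, long-lived
products 35, short-lived products 2, landfill 29.  Landfill chain:
50 % of decayed LLP carbon enters landfill; 20 % of landfill releases
are CH4; GWP100 = 28.  These are literature-informed config defaults
(product half-lives follow common harvested-wood-product practice;
landfill parameters reflect that much buried wood carbon never
degrades and that landfill gas is partially captured or oxidized).

## Products

All volumes are m³ roundwood equivalent at raw-harvest density
(0.48 t dry matter/m³, carbon fraction 0.5 ⇒ 0.24 tC/m³).  Consuming
one unit of processed product requires `ratio ≥ 1` units of roundwood;
defaults are 2.0 for long-lived products and 2.4 for virgin pulp, with
paper demand first reduced to its 40 % virgin-pulp share.  Processing
losses form a waste stream that satisfies industrial-waste-fuel demand
before any extra harvest is booked; all harvested carbon that does not
end up in final long-lived, paper or fuelwood products is treated as
burned waste in the harvest year.

## Demand

`log C_it = α_i + β_pop log P_it + β_gdp log g_it [+ β_t (year−2000)] + ε`
estimated by within-country OLS (statsmodels, country dummies),
separately for three product categories and for developed vs developing
countries, with and without the time term — 12 variants.  Projection to
2050 applies the elasticities to exogenous growth factors anchored to
each country's 2010 consumption (2006–2014 mean), then interpolates
linearly to get annual demand.  Zero or missing consumption-years are
dropped before the log transform.  Trade stays at base-year structure:
fixed net-import shares of consumption, exporters covering global
imports in fixed proportions, so global production equals global
consumption exactly.  Industrial-waste fuel is not regression-projected;
it scales with the other categories whose waste feeds it.

## Supply scenarios

Plantations are harvested first: the 2010 estate is a rotating pool
with annual capacity `area/rotation × yield(rotation age)`, and a slot
re-used one rotation after its last cut adds no new area ("repeated
harvests of a hectare count as one").  Secondary forests cover the
residual at their age-specific clear-cut-equivalent yield
`AGB(age)·(1−slash)·efficiency / 0.24`.

Scenario specifics, where the original leaves detail open, are resolved
as follows:

1. baseline: single harvest of middle-aged secondary stands, regrowth
   on the same curve;
2. conversion: harvested secondary stands regrow on the plantation
   curve and re-supply as whole-cohort pulses every plantation
   rotation; their later rotations are already inside the original
   cohort's PDV, so they add no new ledger entries;
3. mixed harvest: half the secondary harvest area comes from stands 40
   years older, valued with their own trajectory;
4. new plantations: a 2 Mha/yr global allowance is distributed over
   tropical countries pro rata to production; cohorts mature after one
   rotation and then supply like a growing estate, valued from the
   planting year against a secondary-regrowth counterfactual on the
   same land.  Allowance hectares that never become needed are not
   harvested and not counted;
5. productivity: plantation `a_max` scaled by 1.25;
6. efficiency: tropical secondary harvests raised to a high-efficiency
   benchmark (default 0.8), affecting both yield and slash;
7. fuelwood: demand multiplier declining linearly from 1.0 in 2010 to
   0.5 in 2050.

Per-hectare PDVs are computed once per country, forest type and
scenario (they do not depend on the harvest calendar year); product
shares for the carbon partition are the scenario-average shares of the
country's harvest.  The "cost at 2010 demand" is an identical run with
consumption frozen at 2010 levels; the difference is the cost of demand
growth.  Substitution savings — 1.2 tC avoided per tC of long-lived
wood in construction (country-specific construction shares) and
0.175 tC per tC of fuelwood — are reported separately and never netted
against biogenic costs.

## Synthetic world

The generator emulates the study conditions: 30 countries sized so
covered 2010 production is ≈3 billion m³ (80 % of a 3.7-billion-m³
world harvest), a 1961–2020 demand panel on a known log-linear surface
(noise SD 0.4, within the 0.32–0.84 residual range typical of such
fits), population growth 0.2–1.5 %/yr and GDP-per-capita growth
0.8–3 %/yr, tropical countries with shorter rotations and lower
efficiencies, and balanced base-year trade.  A single root seed fans
out to named substreams per table, so outputs are byte-reproducible and
adding a generator never disturbs existing fixtures.

What it does **not** emulate: real FAOSTAT measurement error and unit
inconsistencies, country-specific product ratios, age-class inventories
within countries, or any spatial structure.  Passing tests therefore
demonstrate the correctness of the bookkeeping, fitting and allocation
machinery under controlled conditions — not the accuracy of any
real-world national estimate, which requires dropping in real parameter
tables.

## Numerical choices and edge cases

* Decay uses exact half-life semantics in discrete time; `inf`
  half-lives give inert pools.
* Emissions are computed as exact residuals of each partition, so mass
  balance holds to machine precision.
* PDV series shorter than the horizon are zero-padded (no extrapolated
  regrowth beyond the simulated window); longer series are truncated.
* Discounting of CO2e applies 44/12 to carbon fluxes plus the extra
  `(16/12)·GWP100 − 44/12` weight on methane-carbon in the year of
  release.
* A demand mix of zero total harvest yields a degenerate all-waste
  product share and zero areas rather than an error.
* Infeasible inputs (non-declining growth bands, shares not summing to
  one, non-positive yields with positive demand) raise typed errors at
  validation time, before any simulation.

## Problem sizes

Default runs use 30 countries, 40 harvest years and 41–101-year stand
horizons; the full seven-scenario sweep plus sensitivity completes in
well under a minute, and the test suite exercises 100-seed closure and
recovery checks at these sizes.

## Known limitations

* No soil carbon, fire/windthrow mortality, albedo or other biophysical
  effects, and no fossil emissions of wood processing.
* No price-mediated market feedback or leakage; the counterfactual is
  purely biophysical.
* Secondary forests are drawn at a single configured harvest age per
  country (no age-class inventory dynamics).
* The one-year regeneration lag makes repeat-rotation yields slightly
  conservative relative to the booked rotation-age yield.
* Scenario results on synthetic worlds can sit outside the ranges a
  calibrated real-data run would give (e.g. conversion scenarios
  benefit strongly when the drawn plantation curves are much faster
  than secondary ones).
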