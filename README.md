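# grazemap

Spatial modelling of livestock grazing intensity on extensive rangelands.

Where livestock graze, and how hard, is one of the least-known facts about the
world's single largest land use. `grazemap` implements a regional-scale model
that answers it by balancing an energy budget in space: net primary
productivity (NPP) and land cover become a raster of grazeable metabolizable
energy; district livestock statistics, herd age structure, per-head nutritive
requirements and fodder accounting become an annual grazing energy demand per
settlement; and a competitive greedy allocator distributes that demand onto
the raster, pixel by pixel, outward from each settlement. The result is a map
of *grazing intensity* — the fraction of each pixel's biomass energy consumed
— together with per-district calibrated off-take rates, utilized-pasture
extent, and production-expansion scenarios. The package is aimed at landscape
ecologists and land-use modellers; it ships a synthetic-landscape generator so
every stage is testable without proprietary statistics.

## The model

**Supply.** Total NPP `P` (gC/m²/yr) converts to energy density (MJ/m²) as

- grassland & bare soil: `E = (P / 0.47) / 1000 × 8.6`
- cropland (post-harvest residue): `E = (P / 0.47) / 1000 × 0.90 × (1 − 0.48) × 6.0`

with carbon fraction 0.47 gC/gDM, herbage energy 8.6 MJ/kgDM, residue energy
6.0 MJ/kgDM, wheat harvest index 0.48 and 90% of crop biomass aboveground.
Forest, water, ice, artificial surfaces and nature preserves are excluded.
Only ~40% of the ~77% aboveground share of NPP can be removed sustainably, so
the maximum sustainable off-take is ≈30% of total NPP.

**Demand.** For each district × species (cattle, sheep & goats, horses) ×
farm type (agricultural enterprise AE, private farm PF, household HH), head
counts are split into herd age/function groups with province census shares,
multiplied by MJ/head/yr requirements, and reduced by fodder energy allocated
from district fodder production via consumption shares and fodder-unit
conversions. The remainder is grazing demand; grazing/total demand is the
*grazing gap*. District demand is split over settlements by population,
damped by a piecewise-linear livestock-owner fraction (95% of residents up to
1,000, falling to 0.5% at a million).

**Allocation.** Nine species × farm-type groups are distributed in a fixed
order (household sheep-goats first, enterprise horses last) with base search
radii of 2 km (HH/PF sheep-goats and cattle), 5 km (AE sheep-goats and
cattle) and 10 km (horses). Within a group all settlements compete
simultaneously: in rings of radius k·r, settlements take turns claiming their
single best unclaimed pixel (highest energy density, then nearest), each
pixel yielding `off-take rate × pixel energy`, until demand is met or the
landscape is exhausted. Claims are exclusive across the entire run.

**Calibration.** The model is swept over eleven uniform off-take rates
(10%–60% in 5% steps); each district receives the lowest rate at which the
median maximum grazing distance of its household cattle stays below 10 km,
then the model is re-run with per-district rates.

**Scenarios.** Unutilized pasture within 10 km (or 20 km) of a settlement is
evaluated at business-as-usual or maximum sustainable off-take, and converted
to additional beef or milk (either-or) along two labelled paths: area ×
per-area yield, and energy ÷ per-head requirement × per-head product.

## Worked example

```python
import grazemap as g

bundle = g.generate(g.SynthConfig(seed=1))          # 400×400 cells @ 500 m, 150 settlements
res = g.run_pipeline(
    bundle,
    scenario_configs=[g.ScenarioConfig(settlement_radius_km=10.0, offtake_mode="BAU")],
)
nat = res.ledger.national()
print(f"total supply   : {g.total_supply(res.supply)/1e9:.1f} PJ")
print(f"grazing demand : {nat['grazing_demand_mj']/1e9:.2f} PJ (gap {nat['grazing_gap']:.2f})")
print(f"utilized area  : {res.calibrated.utilized_area_km2():.0f} km2")
```

prints

```
total supply   : 61.4 PJ
grazing demand : 2.14 PJ (gap 0.73)
utilized area  : 11371 km2
```

— a 40,000 km² synthetic steppe holding 61.4 PJ of grazeable energy, of which
livestock need 2.14 PJ from pasture (73% of their total demand, the rest being
fodder); meeting that demand at the calibrated district off-take rates (0.10
for eleven districts, 0.15 for one) occupies 11,371 km², about a third of the
grazeable area. The single scenario then reports 10,275 km² of unutilized
pasture within 10 km of a settlement, worth 1.85 PJ at business-as-usual rates.

The same flow is available from the shell:

```bash
grazemap simulate --seed 1 --out work/bundle
grazemap run-all --bundle work/bundle --out work/run
```

which writes the supply raster, demand ledgers, off-take assignment, claim and
intensity rasters, productivity and scenario tables, and a hashed run manifest.

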