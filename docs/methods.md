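# Methods

## Model overview and assumptions

The package balances an annual metabolizable-energy budget in space. Three
assumptions carry the whole construction:

1. **Livestock live where people live.** All grazing radiates from settlement
   coordinates; herd sizes scale with settlement population, damped by an
   owner-fraction curve, because large towns hold proportionally far fewer
   livestock per resident. Wells, outposts and transhumance are not modelled,
   so remote pasture that is actually reached from non-settlement bases will
   appear unutilized.
2. **Livestock are (imperfect) optimal foragers.** Within reach, the most
   energy-dense pixels are grazed first. Mobility differs by species and farm
   type and is encoded entirely in the nine group radii and their fixed
   distribution order.
3. **Energy is conserved.** Demand disaggregation (province → district herd
   ages, district → settlement demand) and allocation (demand → pixels) are
   exact: every disaggregation step reproduces its marginal totals to
   floating-point accuracy, and when all demands are met the consumed energy
   equals the summed grazing demand.

## Parameters that matter

| Parameter | Default | Unit | Meaning |
|---|---|---|---|
| `carbon_to_dm` | 0.47 | gC/gDM | carbon fraction of dry matter |
| `grass_energy` | 8.6 | MJ/kgDM | metabolizable energy of herbage |
| `residue_energy` | 6.0 | MJ/kgDM | energy of crop residue (wheat) |
| `harvest_index` | 0.48 | – | grain / aboveground crop biomass |
| `crop_aboveground_frac` | 0.90 | – | aboveground share of crop biomass |
| `grass_aboveground_npp_frac` | 0.77 | – | aboveground share of grassland NPP |
| `max_aboveground_offtake` | 0.40 | – | sustainable removal of aboveground NPP |
| group radii | 2 / 5 / 10 | km | HH+PF herds / AE herds / horses |
| rate grid | 0.10–0.60 step 0.05 | – | off-take sweep for calibration |
| distance threshold | 10 | km | HH-cattle median max-distance rule |
| dairy fractions | 0.40 / 0.50 / 0.85 | – | AE / PF / HH share of dairy cattle |
| scenario max rate | 0.30 | – | maximum sustainable off-take of total NPP |

The crop residue expression composes the three crop factors as
`residue DM = total DM × aboveground fraction × (1 − harvest index)`, the only
composition consistent with the harvest index being a ratio of grain to
aboveground biomass. The exact sustainable-off-take product is
0.40 × 0.77 = 0.308; the scenario default uses the conventional rounded 0.30.

Nutritive requirements, fodder conversions/shares and per-head product yields
are *data*, not code. The package ships synthetic defaults (flagged as such in
`grazemap.synthetic`): adult requirements of ~26 / 4.2 / 33 GJ/head/yr for
cattle / sheep-goats / horses with age-group and farm-type multipliers, hay at
6.0 and concentrate at 10.5 MJ/kg, and fodder shares of 0.55 / 0.15 / 0.10 to
cattle / sheep-goats / horses (0.20 to non-grazing consumers). These are
plausible magnitudes for extensive steppe systems; real applications must
supply their own tables.

## The allocation engine

The distribution of one group proceeds in *rings*: at ring k every settlement
with unmet demand may claim pixels whose centers lie within k·r of it. The
statement that all settlements compete "simultaneously" is operationalized as
deterministic round-robin: within a ring, settlements take turns in ascending
settlement-id order, one pixel per turn. A turn claims the single best
eligible pixel — ranked by energy density (MJ/m²) descending, then squared
Euclidean distance to the settlement, then row-major pixel index. Ranking by
energy density rather than raw NPP makes grassland and cropland comparable on
the merged supply map; on grassland the two orderings coincide.

The ring advances when no participating settlement can claim, and the group
ends when all demands are met or every remaining settlement's ring already
covers the whole grid (landscape exhausted — a warning, not an error, with
`demand_met=False` recorded). Pixels with zero energy are never claimable:
claiming one would consume nothing and the ring loop could not terminate.
A claimed pixel yields `off-take rate × pixel energy`; the final pixel of a
settlement consumes only the residual demand (partial intensity) but is still
exclusively claimed, which keeps conservation exact at the cost of at most one
under-used pixel per settlement × group. Settlements carry their own
district's off-take rate wherever they graze, and grazing is not clipped at
district boundaries.

Internally each settlement keeps a lazily grown, key-sorted candidate queue
(new annulus pixels are merged and re-sorted at each ring expansion) with a
pointer that skips pixels claimed by competitors; this is pixel-for-pixel
identical to the exhaustive rescan-everything simulator in `tests/oracle.py`,
which the test suite verifies on randomized grids up to 8×8 with up to three
settlements and arbitrary group subsets.

## Calibration

Eleven full model runs (uniform rates 0.10–0.60) record, per settlement, the
maximum grazing distance of household cattle — the group most tethered to its
settlement (household sheep-goats where a district has no household cattle).
Each district gets the lowest rate whose median distance over its *grazing*
settlements is strictly below 10 km. Decisions the rule leaves open, resolved
here: settlements with zero reference-group demand are excluded from the
median (a district whose whole group is fodder-covered has median distance 0
and gets the grid minimum); districts failing even at 0.60 keep that ceiling
(provenance `ceiling`); districts with no household stock at all get no rate
(provenance `none`) and fall back to a configurable default (0.10) in the
final run. Selection is a pure function of the eleven sweep outputs, so the
order in which sweeps are run cannot change the assignment.

## Synthetic landscapes

The generator emulates the statistical structure the model assumes: a
northeast→southwest linear NPP gradient (default 200 → 30 gC/m²/yr) with
mean-preserving multiplicative lognormal noise (σ = 0.25); a cover mosaic
(62% grassland, 8% bare, 15% cropland in contiguous blocks placed in the
productive northern band, 15% excluded classes); a rectangular 4×3 district
partition in two provinces; 150 settlements (40% clustered around six
centers) with lognormal populations (median 800, σ = 1.2); livestock from
per-capita holding rates that put ~60% of stock in households; and fodder
production sized so fodder covers roughly a quarter of total demand. These
defaults make national grazing demand a few percent of total supply energy
and drive most calibrated districts to the lowest rate, with clustered
high-demand pockets calibrating higher — the qualitative regime the model is
designed for. One seed drives independent sub-streams per component, so
bundles are bit-reproducible and adding a component does not disturb others.

What the generator does *not* emulate: settlements are not preferentially
sited on productive land (so the near-settlement supply premium seen in real
settlement networks appears only weakly, if at all), there is no riparian
structure, no spatial autocorrelation in NPP noise beyond the gradient, and
no correlation between farm-type mix and geography. Passing tests therefore
demonstrate the correctness of the accounting and the allocator, not the
realism of any particular national result.

Calibration-recovery fixtures use a small single-district landscape (120×120
cells, four settlements pinned ~30 km apart so their disks never interact,
household cattle only). Demand is rescaled by bisection until the household
cattle median distance brackets the 10-km threshold between the target rate
and the next-lower grid rate, and the bracket is verified by running both
uniform sweeps; a fixture that cannot bracket raises rather than silently
shifting the target.

## Numerical choices

- All energies are 64-bit floats in MJ; PJ appears only in reports
  (1 PJ = 10⁹ MJ). Distances are metres internally, km at the API surface.
- Ring membership and tie-breaking use *squared* distances computed from cell
  centers (`x0 + (col + 0.5)·s`, `y0 − (row + 0.5)·s`); the oracle uses the
  identical expressions, so equivalence checks are exact, not tolerance-based.
- Demand is met when the remainder reaches exactly zero; the `min(yield,
  remaining)` claim rule makes the final subtraction exact, so no epsilon is
  needed.
- Fodder in excess of demand is clamped (grazing demand ≥ 0, gap ∈ [0, 1]).
- Missing NPP on grazeable cover becomes zero energy with a logged warning.
- The owner fraction is constant at 0.95 on [0, 1000] and at 0.005 beyond 10⁶.
- Per-area productivity treats its basis unit as configurable
  (`area_basis_km2`): published tabulations of this quantity are ambiguous
  between t/km² and t per thousand km², and the quotient is reported in
  whichever basis the caller fixes.
- Expansion scenarios report both production-conversion paths (area × yield
  and energy ÷ per-head requirement) side by side because they answer subtly
  different questions and can differ by large factors; neither is privileged.

## Problem sizes

The reference synthetic country is 400×400 cells at 500 m (≈40,000 km²) with
150 settlements; a full pipeline — eleven-rate sweep, calibration, rerun and
four scenarios — completes in seconds on one CPU, and the test suite's oracle
comparisons use grids of at most 8×8. Recovery experiments run 20 seeded
fixtures. These sizes are the package's chosen reference conditions; all are
configurable.

## Known limitations

- No within-year dynamics: annual energy totals cannot represent seasonal
  forage scarcity, late harvests or winter fodder timing.
- No water constraints, fencing or tenure; no herd movement beyond the
  ring-expansion abstraction; no fodder trade between districts.
- Equal per-capita livestock across settlements of similar size within a
  district — real enterprise herds concentrate in particular villages.
- The greedy ranking is a surrogate for foraging behaviour, not a utility
  model; alternative turn orders within a ring are not explored (the
  round-robin interpretation is the only one implemented).
- Camels and wild herbivores are outside the species set.
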