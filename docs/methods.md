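# Model description and methods

`savhyd` couples a daily two-layer soil-water model with biweekly
trait-based vegetation dynamics and annual selective herbivory on a grid of
30 × 30 cells of 5 × 5 m² (2.25 ha), parameterised for a semi-arid Namibian
savanna on loamy sand (MAP ≈ 291 mm, MAT 26 °C). It is built to compare
grazer-dominated against browser-dominated land use across stocking rates,
and to quantify the consequences for community composition, diversity and
ecosystem water use.

## Climate generator

Daily rainfall is a Bernoulli wet/dry-day process restricted to the
October–April wet season (wet-day probability 0.18) with gamma-distributed
event depths (shape 0.85, mean derived from the MAP target so that the
expected annual sum equals 291.3 mm). A per-rain-year gamma multiplier
(shape 5, mean 1) on event depths supplies the inter-annual variability
that a stationary daily process cannot: without it the annual-sum CV is
≈ 0.2, far below the observed spread of roughly 50–840 mm around a 291 mm
mean; with it, 30 × 100-year batches span that range. Temperature is a
single annual harmonic solved to pass through the June (19 °C) and October
(29 °C) monthly means around a 26 °C annual mean, plus i.i.d. Gaussian
daily noise (sd 2 °C). Years are 365 days; rain years run 1 July–30 June so
a wet season is never split.

The generator is an emulation: the event-depth family, wet-day persistence
and within-season structure of the original satellite-calibrated series are
not public, so only the constraints above (seasonality, MAP, annual-sum
spread, temperature normals) are honoured.

## Hydrology

Each cell holds surface water plus two soil buckets: 0–300 mm and
300–1000 mm depth (volumetric moisture θ). Loamy-sand parameters: porosity
0.437, field capacity 0.125, residual 0.035, soil wilting 0.055, Ksat
1500 mm/d. The daily order of operations is fixed: precipitation →
infiltration → lateral routing → percolation → upper-to-lower diffusion →
bare-soil evaporation → transpiration.

* Infiltration = min(supply, pore space, Ksat·(0.4 + 0.6·cover)): roots
  raise infiltrability.
* Routing moves surface water to the steepest-descent neighbour, scaled by
  (1 − 0.8·cover); lateral boundaries are closed so grid totals are
  conserved. On the default flat terrain (the study site is nearly level
  and events rarely exceed infiltrability) runoff is zero, matching the
  observation that almost all rain infiltrates locally.
* Percolation drains upper-layer excess over field capacity into the lower
  bucket; lower-layer excess over field capacity leaves as deep drainage.
  A small constant diffusion (0.02 mm/d) trickles from the upper to the
  lower layer when the upper is wetter; capillary rise is zero.
* Potential evapotranspiration is a temperature-only Hargreaves-type proxy,
  PET = 0.0023 · Ra(d) · (T + 17.8), with Ra(d) a fixed seasonal radiation
  proxy (mean 50, 18 % amplitude, austral-summer peak). No other
  atmospheric forcing exists in the model.
* Evaporation = PET · 0.10 · relative wetness · (1 − 0.8·cover), drawing
  the upper layer no lower than residual moisture. The constant 0.10 folds
  soil-crust suppression into one calibrated multiplier.
* Transpiration per strategy type and layer is
  PET · cover · UptakeRate · root fraction · g(θ), with g rising linearly
  from 0 at the type's wilting point to 1 at field capacity; withdrawals
  are rationed proportionally if joint demand exceeds the water available
  above the wilting point. Annual grasses root only in the upper layer;
  perennials split 0.8/0.2 and shrubs 0.3/0.7 across the layers.

Water balance closes to better than 1e-9 mm per cell-day (tested). A fused
compiled kernel executes this step in scenario runs; a regression test pins
it to the composed reference implementation at machine precision.

This layering produces the classic two-layer coexistence feedback: a dense
grass sward intercepts upper-layer water so percolation events become rare
and the deep layer — the shrubs' main supply — stays near the shrub wilting
point; removing grass re-opens deep recharge and releases shrub growth.

## Vegetation dynamics

21 strategy types populate three meta-PFTs (9 perennial-grass, 11 shrub,
1 annual-grass type). Within the wet season — the span between the first
and last daily rain event ≥ 5 mm of the hydrological year — cover updates
every 14 days:

* Growth: Δcover = T_veg · WUE · (mm transpired that fortnight) ·
  free space, capped per meta-PFT (perennial 0.10, shrub 0.003, annual 0.15
  per fortnight). WUE = 0.005 cover/mm is global.
* Dispersal: grass seed input is the mean cover over a ~150 m²
  neighbourhood (focal cell + 4 orthogonal neighbours at full weight +
  diagonals at quarter weight — six cells' worth of area, orientation-free);
  shrub seeds follow an exponential kernel (mean 1 cell) plus Poisson
  long-distance events whose rate scales with animal density
  (rate 2.5 · cells / effective SR per fortnight).
* Establishment converts seed availability to cover at per-meta rates
  (perennial 0.03, shrub 0.022, annual 0.075 per fortnight) when the
  fortnight's mean upper-layer moisture clears the type's wilting point by
  0.005 (a 0.02 margin blocks establishment entirely at this site's
  moisture levels). Increments are stochastically rounded in 0.001-cover
  quanta so rare types are not deterministically truncated. Two microsite
  rules shape the establishment niche:
  - shrub recruitment carries an extra free-space factor (quadratic
    overall): woody seedlings need open ground, so a closed sward blocks
    encroachment — without this rule shrubs competitively exclude grasses
    everywhere;
  - the annual flush scales with the square of ground not held by grasses
    (shrub canopies leave the ground layer germinable), which concentrates
    annuals in degraded, shrub-encroached landscapes and keeps them rare in
    dense perennial swards.
* Seed banks: grass and shrub seed pools turn over within a season (decay
  0.5 per fortnight); the annual seed bank is durable — no within-season
  decay, 0.9 carry-over between years, three seeds' worth set per unit
  cover, capped at 1 — giving annuals the storage effect that lets them
  persist through closed-canopy phases and flush after disturbance. Annuals
  shed seed before the end-of-season herbivory, so grazing of the standing
  annual crop does not destroy the next generation.
* Mortality acts once per year at the end of the fixed growing season
  (30 April): survival = 1 − mrd·(0.2 + 0.8·stress), where stress is the
  fraction of growing-season days the root-zone moisture
  (root-fraction-weighted θ) sat below the type's wilting point. Annuals
  die back completely. Per-cell total cover never exceeds 1; increments
  competing for the same space are scaled proportionally.

## Herbivory

Once per year (30 April), standing cover converts to biomass,
BM = cover · conv · cf_rain, with conv = 14 (perennial), 150 (shrub), 3
(annual) kg per full-cover cell and cf_rain = clip(annual rain / MAP, 0.2,
2). Herd demand is 450 kg/LSU · 365 d · 2 %/d · area / SR. The edible share
of each type is 1 − defense, where defense is the defended biomass fraction
(the trait tables give shrubs 0.95 against grazers and perennials 0.95
against browsers — only this orientation is consistent with defense being
beneficial). Cells are visited in random order; a visited cell loses all
its edible biomass unless remaining demand is smaller, in which case the
remainder is split across the cell's types in proportion to
palatability × edible mass. Unmet demand is recorded as a deficit
(supplemental feeding keeps SR constant) but scales down the effective
animal density used for seed dispersal the following season. Remaining
biomass converts back to cover by the exact inverse.

Because visited cells are stripped wholesale, palatability differences act
only in the single marginal cell: herbivory is selective between
meta-PFTs (through defense and pool sizes) but exerts almost no selection
among types within a meta-PFT. This is a faithful reading of the published
removal rule and the main reason within-group cover differences stay
smaller here than in the original study (see Limitations).

## Strategy types and the calibration harness

Each two-letter type takes the +10 %-cover value of its specialisation
trait (capital letter) and the −10 % value of its trade-off trait
(lowercase) from the built-in reference table, calibrated separately for
grazer- and browser-dominated land use; all other traits keep the meta-PFT
defaults (perennial: T_veg 0.5, mrd 0.54, uptake 0.9, wilting 0.077;
shrub: 0.15, 0.12, 0.5, 0.076; annual: 0.6, 1.0, 0.45, 0.0775). The
calibration harness reproduces the table's construction: a trait is scanned
over ±30 % of its default (7 settings) in a four-type community — altered
type and same-meta base dynamic, the other two meta base types frozen at
their 20 % initial cover but still transpiring — at 40 ha/LSU; a linear
regression of last-20-year cover on the trait value is fitted (replicates
pooled), and the ±10 %-cover trait values are read off the line when the
slope is significant at p < 0.05. A self-consistency test rebuilds a type
from the fitted value and verifies the achieved cover deviation within
±3 percentage points.

## Scenarios and outputs

Scenario runs default to 100 years × 30 climate replicates; shrubs and
perennials initialise at 20 % meta-cover (split equally among types),
annuals at 5 %. Randomness is keyed by (master seed, replicate, year,
process) so replicates are order-independent and diagnostics never perturb
trajectories. Annual records per replicate: standing cover per type at
growing-season end net of herbivore offtake (before mortality), annual
upper-layer transpiration and evapotranspiration sums (T/ET uses the upper
layer: T / (T + E)), mean upper-layer moisture over the variable wet
season, and the herbivory ledger. Headline statistics are means over the
last 20 years × replicates.

Diversity uses a strict 2.5 % total-cover threshold for richness; Shannon
and Pielou use natural logarithms (J := 0 for a single-type community).
Community structure comes from an unrotated eigendecomposition of the
correlation matrix of the (observations × types) cover table, retaining
eigenvalues > 1 capped at two factors, signs oriented so shrub + annual
types load positively on factor 1; k-means (k = 2, 50 restarts, fixed
seed) on the type loadings yields within-cluster sums of squares, and
functional dispersion is the abundance-weighted mean distance of types to
the abundance-weighted centroid, computed in the two-factor loading space
by default (raw trait coordinates are also supported).

## Problem sizes

Full-scale runs (30 replicates × 100 years) take a few minutes per scenario
on one core. The package's reproduction harness (`scripts/acceptance.py`)
runs the four headline scenarios at 20 replicates × 100 years — the means
it reports are unchanged in expectation, only slightly noisier — and the
climate statistic at the full 30 × 100 years. The test suite runs the
qualitative land-use panel at 8 replicates and the calibration
self-consistency check at 6 replicates × 50 years.

## Numerical choices

Moisture states are clipped to [residual, porosity]; transpiration is
rationed against available water above the smallest wilting point present;
soil-calibration grid search scans candidates in deterministic order and
keeps the first minimum on ties; k-means seeding is fixed; stochastic
rounding uses the run's keyed RNG streams. The compiled kernel and the
modular numpy path are interchangeable (non-flat terrain automatically uses
the numpy path, which includes lateral routing).

## What the generator does and does not emulate

Synthetic climate reproduces seasonal timing, the MAP, the annual-sum
spread and temperature normals, but not observed wet-spell persistence,
3-hourly structure or any specific historical sequence. The flat default
terrain removes run-on/run-off redistribution. Soil-moisture dynamics are
bucket-model approximations; simulated wet-season moisture (≈ 8.5–9.5
vol %) runs drier than the field-calibrated original (≈ 11.4 vol %).
Passing tests therefore demonstrate internal consistency and the
qualitative land-use contrasts, not site-level predictive skill.

## Known limitations

* Grazed landscapes retain high total cover (woody + annual) instead of
  developing the bare ground seen in the field; erosion, trampling and
  soil-degradation pathways are absent, so total-cover contrasts between
  land uses are weaker than observed, and the grazing-scenario
  transpiration share of ET stays high (≈ 75 % rather than ≈ 62 %).
* Whole-cell biomass removal leaves palatability trade-offs nearly neutral
  within meta-PFTs, so strategy-type covers spread less than in the
  original study; richness counts at the 2.5 % threshold run high where
  many types straddle it, and the factor-space geometry (functional
  dispersion, cluster tightness) differs accordingly.
* Functional dispersion computed in correlation-loading space is bounded
  near √2·(half the loading-space diameter) ≈ 1.4, so reported literature
  values above that cannot be matched under this construction regardless
  of parameters.
* Fire, mixed feeders, animal movement and within-season grazing dynamics
  are out of scope.
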