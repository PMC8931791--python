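# savhyd

Grid-based ecohydrological simulation of a semi-arid savanna under
contrasting herbivore land use: **grazer-dominated** (cattle-style, feeding
on grasses) versus **browser-dominated** (wildlife-style, feeding on woody
vegetation) herds across stocking rates. The package is for rangeland and
savanna ecologists who want a process-level sandbox for bush encroachment,
tree–grass coexistence and the coupling between plant community composition
and ecosystem water use.

## What it simulates

A 30 × 30 grid of 5 × 5 m² cells (2.25 ha) of Namibian-style savanna on
loamy sand (MAP ≈ 291 mm falling October–April, MAT 26 °C), over 100-year
runs replicated across stochastic climate series:

* **Hydrology (daily)** — surface water and two soil layers per cell:
  infiltration, lateral routing, percolation, diffusion, bare-soil
  evaporation *E* and per-type transpiration *T*, each coupled to
  vegetation cover. Water balance closes to < 1e-9 mm per cell-day.
* **Vegetation (biweekly, wet season)** — 21 plant strategy types in three
  functional groups (9 perennial grasses, 11 shrubs, 1 annual grass), each
  specialised (+10 % equilibrium cover) in one trait and handicapped
  (−10 %) in another, among biomass production *B*, mortality *M*,
  palatability *P*, defense *D*, water competitiveness *C* and drought
  resistance *R*. Growth is transpiration-driven
  (ΔC = T_veg · WUE · T · free space); dispersal, microsite-limited
  establishment and end-of-season drought/senescence mortality complete the
  cycle.
* **Herbivory (annual)** — the herd's fodder demand
  (450 kg/LSU · 2 %/day · area / SR, Eq. *NeededBM*) is filled by visiting
  random cells; biomass is BM = C · conv · cf_rain with a rainfall
  correction factor, each type shields a defended fraction of its biomass,
  and food deficits reduce the effective animal density that disperses
  shrub seeds.
* **Analytics** — richness above a 2.5 % cover threshold, Shannon *H* and
  Pielou *J = H/ln S*, two-factor structure of the cover matrix, k-means
  cluster tightness (WCSS), abundance-weighted functional dispersion
  (FDis), Cohen's *d*, ε², and the transpiration share of
  evapotranspiration (T/ET) as the "productive" green-water fraction.

The coexistence engine is the classic two-layer mechanism: dense perennial
grass pre-empts upper-soil water so deep percolation — the shrubs' supply —
almost stops; removing grass (heavy grazing) re-opens deep recharge and
releases shrubs and annuals (bush encroachment). Browsers instead suppress
the woody layer and keep the grass matrix closed.

## Worked example

```python
import numpy as np
import savhyd as sv
from savhyd.runner import ScenarioConfig, run_scenario, summarize_last20
from savhyd.metrics import shannon_pielou, water_use

clim = sv.generate_replicates(sv.ClimateConfig(), years=100, replicates=5, seed=42)
sums = np.concatenate([c.annual_sums() for c in clim])
print(f"climate: MAP {sums.mean():.1f} mm, annual range {sums.min():.0f}-{sums.max():.0f} mm")

cfg = ScenarioConfig(land_use="browsing", stocking_rate=20, years=100,
                     replicates=5, seed=42)
s20 = summarize_last20(run_scenario(cfg, clim))
stats, tc = s20["stats"], s20["type_cover"]
print(f"total cover {stats.loc['total_cover_pct','mean']:.1f} %, "
      f"T/ET {water_use(stats.loc['t_mm','mean'], stats.loc['et_mm','mean']):.1f} %")
print(f"richness {shannon_pielou(tc.to_numpy()).S} types > 2.5 % cover")
```

prints (about half a minute on one core):

```
climate: MAP 288.3 mm, annual range 51-1001 mm
total cover 87.2 %, T/ET 83.1 %
richness 9 types > 2.5 % cover
```

i.e. under heavy browsing the perennial grass matrix stays closed (the
dominant types are drought-resistant perennials), nearly all green water
leaves through plants rather than bare-soil evaporation, and all perennial
strategy types persist. Running the same configuration with
`land_use="grazing"` collapses the perennial layer and shifts the
landscape to shrubs and annuals.

## Command line

```bash
savhyd generate-climate --years 100 --replicates 30 --seed 1 --out climate/
savhyd run --scenario browsing --sr 20 --seed 1 --out runs/browsing_20
savhyd analyze --in runs/browsing_20 --out analysis/
savhyd calibrate-strategies --meta perennial --parameter t_veg \
       --land-use grazing --seed 1 --out scan.csv
```

Outputs are tidy CSVs (per-year cover by type, water fluxes, herbivory
ledger) plus a JSON manifest with the config hash and master seed;
identical seeds reproduce outputs byte-for-byte.

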