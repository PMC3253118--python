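# habsuit

Presence-only habitat suitability mapping for allopatric lineages.

`habsuit` predicts where a species could live from nothing but museum-style
occurrence records (species, longitude, latitude) and four global
environmental raster layers: elevation (**ALT**, m), annual mean temperature
(**TMA**, °C), annual mean precipitation (**PMA**, mm) and categorical land
cover (**GLC**, codes 1–23, water = 20). It targets lineages of closely
related, geographically non-overlapping (allopatric) species — each species
gets its own model inside its own potential range — and was designed around
the kind of data a taxonomic revision produces: a few dozen to a few hundred
georeferenced specimen records per species and no absence data at all.

## The model

For each species with enough records the pipeline runs six stages:

1. **Attribute extraction.** Each record samples the four layers at its
   containing cell (cell-centre registration); records on NoData or water are
   dropped. All distances and areas are computed in a Lambert cylindrical
   equal-area projection.
2. **Variable screening (OLS + VIF).** A global linear model regresses a
   presence-intensity response
   `y_i = ln(1 + #conspecific records within 100 km)` on the four parameters.
   Predictors with variance inflation factor `VIF_j = 1/(1 − R²_j) > 7.5`
   are removed one at a time, then the least significant predictor (largest
   heteroskedasticity-robust probability) is removed until the two best-fit
   parameters remain.
3. **Geographically weighted regression.** The selected pair is refit
   locally at every record with bisquare kernel weights
   `w = (1 − (d/h)²)²` and adaptive bandwidth `h_i` = distance to the
   10th nearest neighbour. Reported diagnostics: local coefficients, hat
   trace tr(S), R², adjusted R², and the small-sample corrected
   `AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)`.
4. **Residual diagnostics.** Global Moran's I on the GWR residuals
   (inverse-distance weights, row-standardized), with `E[I] = −1/(n−1)`,
   randomization variance, z-score, two-sided p, and a pattern label
   (random / quasi-random / quasi-clustered / quasi-dispersed / clustered /
   dispersed). A good model leaves random residuals.
5. **Directional distribution.** A standard deviational ellipse centred on
   the mean of the projected records, semi-axes of **three** standard
   deviations along the rotated principal axes (no small-sample
   correction), covering ≈ 99% of normally scattered points. Terrestrial
   cells inside the ellipse are the species' potential target area.
6. **Frequency-class mapping.** For each selected parameter, the values
   observed at the records are binned (ALT 100 m, TMA 1 °C, PMA 100 mm,
   GLC by category) and the occupied bins split into high/moderate/low
   frequency terciles. Cells in the target area are ranked 3/2/1 through
   these classes (never-observed values → NoData), the two rank rasters are
   averaged with equal weight, smoothed with a circular focal mean of
   radius 9 cells, and cut into the final high/moderate/low map on equal
   thirds of [1, 3].

## Worked example

`examples/06_full_suitability_map.py` builds a seeded synthetic study region
(four 100×100 layers at 0.5°, a warm-lowland species with a
TMA 20–32 °C × ALT 0–1000 m niche, 300 records) and runs the whole chain:

```
species       : synthetic_sp (300 records)
selected pair : ['ALT', 'TMA']
OLS  AIC=577.3  adj R2=0.76
GWR  AICc=36.5  R2=0.99  adj R2=0.99
Moran I=+0.0020 (E[I]=-0.0033) -> random
suitability cells:
  outside/NoData : 3090
  moderate       : 4087
  high           : 2823
truth-niche cells rated >= moderate: 100%
```

The screening recovered exactly the two parameters that generated the
species (ALT, TMA); the locally weighted fit is far stronger than the global
one (AICc 36.5 vs AIC 577.3, R² 0.99 vs 0.76), its residuals are spatially
random (Moran's I ≈ E[I], p ≫ 0.05), and every cell of the true niche that
falls inside the ellipse is rated moderate or high. The other examples
exercise each stage on its own and print what the numbers mean.

## Command line

```
habsuit run --localities locs.csv \
    --raster ALT=alt.asc --raster TMA=tma.asc \
    --raster PMA=pma.asc --raster GLC=glc.asc \
    --species "My species" --out results/
```

Subcommands `select`, `gwr`, `moran`, `ellipse`, `rank` expose individual
stages; `fixtures make` writes a synthetic raster quartet + locality CSV;
`report` prints the per-species metric table of a finished run. Exit codes:
0 ok, 1 usage, 2 input, 3 numerical failure.

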