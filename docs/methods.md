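# Methods

This note records the modelling assumptions, parameter defaults and design
choices behind `habsuit`, and what the synthetic tests do and do not show
about real data.

## Scope and assumptions

The pipeline is a presence-only, frequency-based habitat suitability model.
Its core assumptions:

- **Occurrence density reflects suitability.** Environmental values that
  occur often at known records are treated as highly suitable, rare values
  as marginally suitable, values never observed as unsuitable. Collection
  effort is taken as roughly proportional to true occurrence — untrue for
  strongly biased sampling (roadside collecting, museum-era gazetteers).
- **The potential range is the 3-SD deviational ellipse.** Dispersal limits
  are summarized by a single ellipse over the projected records; this
  ignores barriers, competitors and human-mediated transport.
- **Allopatry.** Each species is modelled alone within its own ellipse;
  interspecific competition is not represented.

## The response variable

The screening regression needs a numeric response, but presence-only data
have none. The package's default is a local presence intensity,

    y_i = ln(1 + number of other conspecific records within 100 km of record i),

computed in the equal-area projection. It is smooth, always defined, and
increases where the species is densely recorded. It is an *assumption*, and
it is flagged in every report: absolute fit metrics (AIC, R²) depend
entirely on this choice, which is why the package's validation rests on
relative and structural properties (selection recovery, GWR-beats-OLS,
residual randomness) rather than on reproducing any particular printed
fit-statistic magnitudes. The radius is configurable
(`response.radius_km`); any numeric column can be designated the response
instead.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `selection.vif_threshold` | 7.5 | collinearity removal threshold |
| `gwr.k_neighbors` | 10 | adaptive bandwidth = distance to k-th neighbour |
| `ellipse.n_sd` | 3 | deviational-ellipse axis scaling |
| `focal.radius_cells` | 9 | circular focal-mean radius (cell units) |
| `bins.alt_width` | 100 m | ALT frequency-bin width |
| `bins.tma_width` | 1 °C | TMA frequency-bin width |
| `bins.pma_width` | 100 mm | PMA frequency-bin width |
| `min_records` | 30 | species below this are skipped, with a report entry |
| `moran.scheme` | inverse_distance | spatial weights, row-standardized |

The bin widths match the effective precision of 1-km global layers; all are
configurable. The focal radius is specified in cell units; its kilometre
equivalent is reported from the grid's cell size (≈ 8.7 km at 1-km cells)
but never enforced.

## Statistical conventions

- **Projection.** Lambert cylindrical equal-area on the authalic sphere
  (R = 6 371 007.181 m), standard parallel 0. Equal-area by construction;
  round-trip error < 1e-6°.
- **OLS.** Fit by `statsmodels`; robust probabilities from the HC0 (White)
  covariance with t-distribution inference on n − k − 1 df. AIC is the
  Gaussian-likelihood form `n ln(2π·SSE/n) + n + 2(k+1)`. Land cover enters
  as its numeric code by default (a one-hot option exists); this mirrors
  how a single-band categorical layer behaves in a generic regression tool
  and is a known crudity.
- **VIF.** Auxiliary regression of each predictor on the others,
  `VIF = 1/(1 − R²_aux)`; exact collinearity reports `inf` rather than
  raising, so the backward-elimination stage can resolve duplicated
  columns itself. A single predictor has VIF 1 by definition.
- **Elimination order.** All VIF removals precede significance removals;
  elimination always terminates at exactly two predictors even if more
  remain significant, because the mapping stage consumes exactly two.
- **GWR.** Adaptive bisquare kernel; bandwidth = distance to the k-th
  nearest neighbour (coincident points fall back to the nearest distinct
  distance). Locally singular designs (duplicate coordinates among the k
  neighbours) get a 1e-8 ridge and a warning. AICc uses the standard
  small-sample geographically-weighted form with the hat trace as the
  effective parameter count; `n − 2 − tr(S) ≤ 0` reports AICc as
  undefined rather than a number. GWR here is diagnostic — suitability
  comes from frequency classes, not from GWR prediction — so no prediction
  at unsampled locations is performed. A near-flat `boxcar` kernel exists
  as a test hook to verify convergence to global OLS.
- **Moran's I.** Features are unique record coordinates (mean residual per
  coordinate): duplicate localities carry no additional spatial
  information, and the feature count in the report is therefore generally
  smaller than the record count. Variance under the randomization
  (permutation-moment) assumption; a seeded Monte-Carlo permutation
  p-value (999 permutations) is available as a cross-check. Pattern labels:
  p ≥ 0.10 random; 0.05 ≤ p < 0.10 quasi-random; 0.001 ≤ p < 0.05
  quasi-clustered/quasi-dispersed by the sign of I − E[I]; p < 0.001
  clustered/dispersed.
- **Deviational ellipse.** Rotation from
  `tan θ = [(Σx′² − Σy′²) + √((Σx′² − Σy′²)² + 4(Σx′y′)²)] / (2Σx′y′)`
  (θ clockwise from north, deviations from the coordinate mean); semi-axes
  are `n_sd · σ` along the rotated axes with **no** √2 small-sample
  correction. The uncorrected 3-SD ellipse contains `1 − e^{−9/2} ≈ 98.9%`
  of bivariate-normal points — the "approximately 99%" convention; the
  corrected variant would cover 99.99% and was rejected on that ground.
  The polygon is discretized at 360 vertices.
- **Frequency classes.** Continuous bins are half-open `[a, b)` anchored at
  integer multiples of the width. Classes are count terciles over occupied
  bins (thresholds at the 66.7th/33.3rd percentiles), ties promoted
  upward, so equal-count bins all rank high; an explicit bin→class map can
  override. Values outside every occupied bin are outliers → NoData.
- **Map algebra.** Combination is the arithmetic mean of the two rank
  grids (keeps the 1–3 scale interpretable); NoData in either input
  propagates. The focal mean ignores NoData neighbours, clips at grid
  edges, and never fills a NoData centre — smoothing must not invent
  suitability outside the ranked domain. Smoothing precedes the final
  classification; the classification cuts [1, 3] into equal thirds with
  boundaries assigned upward. Both the sum-combination and
  classify-before-smooth orders are deliberately not offered: the mean +
  smooth-then-classify order is the package's single, documented
  convention.

## The synthetic study region

`gen_env_rasters` builds a 100×100-cell, 0.5°-resolution (roughly
continental) region: ALT, TMA and PMA are independent seeded Gaussian random
fields (smoothed white noise) rescaled into realistic sub-ranges of the
documented global ranges (ALT 0–3350 m, TMA −5–32 °C, PMA 0–4000 mm); GLC
is a categorical mosaic over 11 land classes plus a contiguous water fraction
(default 12%). Elevation and temperature vary at a 4-cell correlation
length, precipitation and land cover at 1 cell — orographic rainfall and
land-use patches genuinely vary at much shorter ranges than continental
relief, and this scale separation is also what makes the generative signal
identifiable: a smooth decoy field over a domain with few independent
patches can align with any clustered response by chance.

`gen_localities` samples a warm-lowland species: records are a mixture of
75% in-niche draws (cells with TMA ∈ [20, 32] °C and ALT ∈ [0, 1000] m,
weighted `exp(1.5·score)` toward the warm/low optimum — abundance declines
toward tolerance limits rather than dropping off a cliff) and 25% uniform
background over land, jittered inside their source cell so each record
samples exactly that cell, never on water. Ground-truth labels (which draws
were in-niche, the niche cell mask) are returned for recovery tests.

What passing tests on this generator do **not** show: robustness to
collection bias, to spatially correlated cross-field structure (real
temperature does lapse with elevation — deliberately absent here because it
makes the two niche axes partially confounded), to coastline geometry, or
to the highly non-Gaussian value distributions of real precipitation.

## Problem sizes

The test suite and examples run the full chain at 100×100 cells and
200–300 records per species, selection-recovery harnesses at 50 seeded
fixtures, Monte-Carlo checks at 1e5 points (ellipse coverage) and 500
simulations (Moran type-I calibration) — sizes chosen so every property is
measurable with comfortable statistical margin while the whole suite stays
fast.

## Known limitations

- The response-variable definition is an assumption (see above); reports
  carry a note saying so.
- GLC as a numeric code imposes a spurious ordering on land-cover classes.
- The frequency-class cut points are count terciles; with very few occupied
  bins the three classes can collapse (a single bin is simply "high").
- The Moran feature-collapsing rule (unique coordinates) is a convention;
  other reasonable rules (e.g. graticule snapping) would change n and
  thus E[I].
- The ellipse is a single global summary; disjunct ranges (e.g. an
  introduced population on another continent) inflate it severely.
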