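# Methods

This note documents the models, numerical choices, and calibration
studies behind `firesev`, in the spirit of a statistical-software
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The outcome model

High-severity occurrence is modeled as a Bernoulli outcome per 30 m
pixel with a logit link:

```
logit P(high severity) = β₀ + Σ βⱼ xⱼ + Σ γⱼ (HDW · xⱼ) + ownership + fire id
```

All continuous covariates are standardized (population sd), so
coefficients are log-odds per one sd. The default synthetic-truth
coefficient vector is the stand-scale effect set the package is built
around: stem density 0.32, hot-dry-windy index (HDW) 0.41, ladder fuels
0.21, spatial homogeneity 0.13, mean height −0.10, fuel moisture −0.13,
and interactions HDW×density 0.15, HDW×height 0.15, HDW×ladder −0.063.
Homogeneity never interacts with HDW (it is nearly collinear with
density, which would make the interaction uninterpretable). The default
intercept 0.26 = logit(0.565) reproduces a public-land base rate of
56.5%. Ownership offsets default to +ln 1.45 (private industrial) and
−ln 1.45 ("other") relative to public land.

Fits use iteratively reweighted least squares with a deviance
convergence tolerance of 1e-8, linear predictors clipped to ±30, and
working weights floored at 1e-10. Quasi-separation is flagged (not
raised) when any coefficient exceeds 25 in absolute value or the
deviance is essentially zero. IRLS was written in-house because the
bootstrap and coverage studies need on the order of 10⁵ refits;
correctness is cross-checked in the tests against both a generic BFGS
maximum-likelihood fit and statsmodels' GLM (agreement ≤ 1e-6 / 1e-8).

## Structure metrics

* **Windows.** 90 m and 390 m square windows centered on each pixel
  (odd multiples of the pixel size, so boundaries align). At the
  landscape edge the window is clipped and the clipped area A used; a
  strict mode (`edge="strict"`) that returns NaN instead is available.
* **Homogeneity.** The uncorrected Clark–Evans ratio
  h = mean nearest-neighbor distance / (½√(A/N)) with N and A from the
  clipped window and neighbors restricted to the window. No edge
  correction is applied (the printed form of the metric). This form has
  a known positive bias under complete spatial randomness of order
  8(0.0514 + 0.041/√N)/√N (≈ 3% at N = 200, the Donnelly boundary
  term): points near the window edge cannot see neighbors outside it.
  `csr_homogeneity_experiment` measures this directly; the measured CSR
  mean at N = 200 is ≈ 1.03, not 1.00, and users comparing h across
  window sizes should expect the bias to shrink as N grows. The moving-
  window implementation reads each stem's within-window nearest
  neighbor off a precomputed global k-nearest list with an exactness
  certificate (candidate distance ≤ k-th global distance) and a brute-
  force fallback, so results equal the direct computation exactly.
* **Gaps.** Crowns are rasterized at 0.75 m (the canopy-height-model
  cell size of the source data); gaps are 8-connected uncovered
  components clipped to the window; the metric is their mean area. A
  fully covered window scores 0; a crownless window scores the window
  area.
* **Ladder fuels.** Computed per pixel only. Simpson evenness is taken
  over bands 1..q (q = tallest occupied band), the cover mean μ_c over
  all four bands; the all-zero profile scores 0. Evenness equals 1
  exactly when all four bands share one cover value.
* **Forest mask.** Strictly more than 10% cover of trees over 4 m.

## Fire timing

Detections are binned into consecutive 8-h windows starting at the
first detection. For window w, the convex hull (optionally a shapely
concave hull) of all detections with t below the window end is buffered
by half the 375 m footprint; a pixel receives the smallest w whose hull
contains its center. Buffering also resolves degenerate (collinear or
single-point) hulls. Incoming severity for a pixel in window w is the
1/d-weighted mean severity of up to 1000 pixels sampled uniformly
without replacement from window w−1; the sample is drawn once per
window (equivalent in distribution to per-pixel draws, and vectorizable),
and all candidates are used when fewer than 1000 exist. First-window
pixels default to the mean window-1 severity (configurable to NaN);
the window clock and the weighting kernel are documented package
choices where the upstream algorithm is underspecified.

## Weather and terrain

Station variables are averaged per burn window first; pixels then
receive a weighted station average with
w ∝ (d + 1 m)⁻² · (|Δz| + 10 m)⁻¹ (exponents configurable). The offsets
keep weights finite while letting a co-located station dominate (within
1% at the station pixel). HDW is window-mean wind × window-mean VPD;
VPD uses the Tetens saturation pressure
e_s = 6.112·exp(17.67 T/(T + 243.5)) hPa. Slope/aspect use Horn's 3×3
differences with replicated edges; TPI subtracts the mean elevation of
all pixel centers within 300 m, focal pixel excluded (a disk, not an
annulus); heat load is the folded-aspect McCune–Keon equation
exp(0.339 + 0.808 cosL cosS − 0.196 sinL sinS − 0.482 cosA_f sinS),
valid for 0–60° N and slopes to 60°, with A_f = |180 − |aspect − 225||.

## The synthetic landscape

The generator emulates the structure of the real inputs, not their
values; passing tests demonstrate algorithmic correctness and
statistical calibration, not realism of any particular forest.

* **Stem patterns**: homogeneous Poisson; Thomas process (Poisson
  parents per ha, Poisson offspring counts, Gaussian dispersal, parents
  drawn in a padded window so edge clusters contribute); hard-core
  sequential thinning of Poisson candidates (realized density below the
  candidate intensity; infeasible spacings are rejected). Heights are
  lognormal truncated at the 4 m detection floor; crowns are circles
  with r = 0.5·h^0.6 capped at 10 m (plausible conifer allometry,
  configurable).
* **Ownership mosaic**: square parcels (default 300 m) labeled
  public / private-industrial / other (0.70/0.20/0.10). Private parcels
  carry dense, evenly spaced, even-height stems; public parcels carry
  clustered, height-diverse stands; "other" is sparse and random.
* **Terrain**: Gaussian-filtered white noise; `correlation_length` is
  calibrated to be the practical semivariogram range (95% sill), and
  relief is exact peak-to-peak. Climatic water deficit is synthesized
  as a smooth elevation-correlated surface because the pipeline only
  ever consumes it as an external covariate raster.
* **Weather**: sinusoidal diurnal temperature (peak 15:00) minus an
  elevation lapse, mirrored humidity, AR(1) wind, humidity-tracking
  10-h fuel moisture; clipped to physical ranges.
* **Fire**: a stochastic cellular front — each half-hour step, unburned
  4-neighbors of the front ignite with probability 0.8 (optionally
  wind-biased). This is deliberately not a physical fire model; it
  exists to provide known burn times. Defaults give a front speed near
  0.7 pixels/step (≈ 40 m per half hour), i.e. a fast fire day, so a
  200×200-pixel landscape yields 6–7 burn windows over 48 h.
  Detections: each newly burned pixel per window is seen with
  probability rate × pixel area, default 7.1 km⁻² per window — one
  detection per 375 m footprint (0.1406 km²) of newly burned area —
  with positions jittered uniformly by ±half the footprint.
* **Severity**: Bernoulli outcomes from the logistic truth; the
  continuous CBI-like value is a deterministic monotone map of the
  model probability within each outcome class, anchored so that high
  severity ⇔ CBI > 2.25 strictly. Any monotone map suffices for the
  classification stages; no claim of CBI realism is made.

## Spatial uncertainty

Square blocks (default side 990 m = 33 pixels, comfortably larger than
the stand window) tile the extent half-open; whole blocks are resampled
with replacement (as many as exist), member rows concatenated, and the
model refit per replicate (warm-started at the full-data estimate);
95% CIs are the 2.5/97.5 percentiles over replicates (default B = 1000;
below 200 is refused, below 1000 warned). Replicates with a
single-class outcome or a rank-deficient design (a categorical level
absent from the resample) are dropped and counted, with a warning above
10%. Setting the block side to one pixel recovers the ordinary
bootstrap. Spatially blocked k-fold assignment partitions blocks, never
rows.

**Coverage study** (`block_coverage_experiment`): 200 landscapes of
50×50 pixels tiled into 100 blocks of 5×5; the covariate has a
block-level share (ρ = 0.7) and outcomes a block random intercept
(σ = 0.7) around a slope of 0.5, giving within-block score correlation
of the kind fire contagion induces. Because random intercepts attenuate
the marginal slope, the coverage target is the probability limit of the
marginal estimator, computed once from an 800k-row fit. With B = 400,
the block bootstrap attains near-nominal coverage while the ordinary
bootstrap under-covers — the motivating property of the design.

## Problem sizes and numerical conventions

Tests and the acceptance script run at sizes chosen to make Monte-Carlo
error small relative to the assertions: coefficient recovery at
n = 50,000 (sampling error ≈ 0.01 per coefficient), coverage over 200
simulations (se ≈ 1.5%), burn-window recovery on a 200×200-pixel fire,
the end-to-end demonstration at 120×120 pixels with B = 400. Brute-force
oracle comparisons use a 20×20-pixel fixture. Window sums use direct
kernel correlation (no sliding subtraction), so windowed counts are
exact and means reproduce brute force to better than 1e-9 relative.
Grids place row 0 at the south edge with half-open pixel membership
(west/south edges inclusive); rasters are flipped to north-up on disk
with a JSON sidecar carrying origin, pixel size, and nodata, and
rotated or non-square geometries are rejected on read. Every stochastic
stage derives its seed from the master seed by stage name; reruns with
an identical configuration produce identical output hashes.

## Known limitations

* The synthetic weather, terrain, and fire models are statistical
  stand-ins; they do not attempt meteorological or fire-behavior
  realism, and conclusions about real landscapes require real inputs.
* The uncorrected homogeneity index is edge-biased upward (~3% at
  N = 200); comparisons across very different stem counts inherit that
  bias.
* The burn-window algorithm assumes an approximately convex,
  single-ignition fire; strongly concave fronts need the concave-hull
  mode, and multiple simultaneous ignitions per fire id are not split.
* Ownership effects in the end-to-end synthetic run are confounded
  with structure by construction (private parcels are denser), so the
  ownership GLM — which controls weather and topography but not
  structure — recovers the combined direct + structure-mediated effect;
  the isolated direct effect is validated separately in
  `ownership_recovery_experiment`.
* Surface fuels, suppression activity, and salvage logging are outside
  the model.
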