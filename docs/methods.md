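# Methods

This note documents the models, the synthetic-data generators and the
numerical choices in `canopybench`, in the spirit of a methods appendix:
what is computed, under which assumptions, and what the defaults mean.

## Problem setting

The response is mean canopy height (MCH): the spatial average of
fine-resolution canopy heights over a 100-m (1-ha) pixel, in metres.
Predictors are co-registered raster bands playing four roles — optical
reflectance (L), L-band radar backscatter (A), interferometric
elevation (S) and derived texture (T).  A regressor trained on a few
hundred sampled pixels predicts MCH wall to wall; the scientific
question is not only overall accuracy (RMSE, R²) but *conditional
bias*: because both optical and radar signals saturate over dense
forest, the signal-to-noise ratio collapses at the tall end and any
conditional-mean estimator drifts toward the sample mean there.

### Tail diagnostics

MSD = mean(predicted − measured).  MSD1 restricts the average to pairs
with predicted + measured < 20 m (small trees); MSD2 to sums > 60 m
(large trees).  The sum-based rule keeps a pair in the "tall" subset
whether the model or the lidar says it is tall, which avoids
conditioning purely on the noisy prediction.  Both rules use strict
inequalities; sums equal to a threshold fall in neither subset, and an
empty subset reports NaN, never 0.  With the predicted−measured sign
convention, underestimation of tall canopies appears as negative MSD2.

## Preprocessing

* Aggregation: each coarse cell is the arithmetic mean of the unmasked
  fine cells in its block.  Partial edge blocks are dropped (no
  padding); a coarse cell is masked only when its entire block is
  masked.  Grid indices are 0-based row-major and pixel (r, c) covers
  the half-open square `[r·s,(r+1)·s) × [c·s,(c+1)·s)` metres.
* Validity: the land-cover mask (binary, consumed not produced) is
  applied first, then pixels with MCH ≤ 1 m are removed; the per-rule
  removal counts are returned.  A pixel failing both rules counts under
  land cover.  Masking is idempotent.
* Rasters are plain TIFF with pixel size, origin and nodata stored as
  JSON in the image description tag; sample tables are CSV with
  row/col/x/y/response followed by one column per band.

## Texture

Two neighborhood summaries per band and scale, at windows 5/9/17/33
pixels with Gaussian σ = 1/2/4/8: the normalized Gaussian-weighted mean
and the local *population* (1/N) standard deviation.  Out-of-grid or
masked neighbors are excluded and the remaining weights renormalized,
so no values are invented at scene edges.  The SD computation centers
the band on its global mean first — a pure numerical-stability measure
(the SD is shift-invariant) that protects the E[z²]−E[z]² form against
cancellation for bands with large offsets.  Texture is computed at the
working 100-m resolution on the co-registered stack.

## MaxEnt class-probability regression

The response is cut into uniform classes (default width 2 m, spanning
(0, max]); empty classes are dropped and each class's nominal value is
the mean of its training responses.  For class k the fitted density is
the Gibbs form `q_k(x) ∝ exp(λ_k·f(x))` over a background sample of the
prediction domain — the maximum-entropy density whose regularized
feature expectations match the class's empirical feature means.  The
per-class problem

    min_λ  −λ·f̄_k + log Σ_bg exp(λ·f(x_b)) − log N_bg + r‖λ‖²

is convex and solved with L-BFGS-B (budget 500 iterations, gradient
tolerance 1e−6; a fit is rejected if the final gradient infinity-norm
exceeds 1e−4).  Choices that the method leaves open:

* **Features** `f(x)`: background-standardized band values plus their
  squares (linear + quadratic constraints).  This is the smallest
  expansion that lets each class carve out an interval of a saturating
  band; hinge/threshold/product features from the species-distribution
  literature are deliberately out of scope.
* **Regularization** r = 0.01 by default — enough to keep sparse
  classes finite, small enough not to flatten the density ratios.
* **Background**: all valid pixels when a scene is available, capped at
  100,000 by seeded uniform subsampling (the benchmark experiments cap
  at 10,000 to keep per-repetition fits to a few seconds).  The raw
  output is the density ratio against the uniform background density,
  computed and combined in log space with per-pixel max normalization,
  so underflow cannot produce a zero denominator.

Prediction is the power-weighted posterior expectation of class centers
with empirical priors N_k/N_total.  `m = 1` is the plain Bayes
expectation; `m = 3` (the MEBC default) concentrates weight on the most
probable classes, pulling tail predictions toward their class centers.
Raising m trades dispersion (worse RMSE/R²) for tail bias — visible in
the benchmark tables.  Predictions are always convex combinations of
class centers.

## Random forest and RFBC

The forest is scikit-learn's `RandomForestRegressor` (500 trees,
max_features = 1/3 of predictors per split, min leaf 5 — common
regression-forest practice; the benchmark conclusions concern relative,
not absolute, forest behaviour).  Out-of-bag predictions are averaged
explicitly over the trees whose bootstrap excluded each row; rows that
appear in every bootstrap receive the full-ensemble prediction and are
flagged, preserving row alignment.  The bias stage trains on the
reflected targets `y_new = 2·ŷ_oob − y` with an independent seed
substream (so the two forests are not tree-for-tree correlated), and
the corrected prediction is `2·ŷ − ŷ_new`.  When the bias stage
reproduces the primary stage's systematic bias b(x), the correction
returns ŷ − b(x); when both stages agree, it is a fixed point.

## Synthetic data

### Tabular noise simulation

Five standard-normal predictors with 0.2 pairwise correlation
(equicorrelated Cholesky draw); `Y = 10·mean(X) + 20` plus Gaussian
noise with sd equal to 10 % of the closed-form noiseless-signal sd
(`10·sqrt((1+4·0.2)/5) = 6.0`, so noise sd 0.6); then additive Gaussian
noise on X with sd 0.2 or 0.8 (fractions of the unit predictor sd).
The fractions are interpreted as fractions of the perturbed quantity's
standard deviation — the only reading consistent with unit-variance
normalized predictors.  X-noise is added *after* Y is computed, so the
80 % scenario models sensors that have lost most of their sensitivity
to the response.  Default n = 10,000 with a random half/half
train/test split (the split mode and n are configurable).

Because the 20 m/60 m thresholds are MCH-specific, the simulation
experiment re-expresses the tails two ways, and emits both: (a) sums
below/above the 10th/90th percentile of 2·Y, and (b) the fixed response
windows 5 < Y < 6 and 34 < Y < 35 (≈ ±2.4 signal sd around the
intercept), reported as `msd_low_y`/`msd_high_y`.  The window variant
probes further into the tails: at 80 % noise it shows the bias that the
correction cannot remove, while the milder percentile tails are largely
correctable even there.

### Synthetic landscape

The MCH field is a Gaussian random field (white noise smoothed at the
autocorrelation length, default 6 pixels = 600 m) mapped through its
empirical rank onto 0.5–45 m.  The rank map is monotone, so spatial
structure is preserved while the height histogram covers the full
range, giving both tails enough pixels for MSD1/MSD2 to be estimated.
The default scene is 180×180 pixels (~32,400 valid 1-ha pixels,
mirroring the scale of a single mapped site).

Each predictor band is a saturating response `1 − exp(−MCH/h)` plus
Gaussian noise with a 3-pixel spatial correlation length:

| band | role | e-folding height h (m) | noise sd (band units) |
|------|------|-----------------------|----------------------|
| L1–L4 | optical | 8, 10, 12, 15 | 0.30 |
| A_HH, A_HV | radar | 20, 28 | 0.22 |
| S_elev | elevation | 90 (≈ linear) | 0.18 |

These values were chosen once to place the raw-band regression problem
in the regime reported for real tropical-forest stacks — R² roughly
0.55–0.85 depending on the input set, large-tree bias (MSD2) of −3 to
−6 m — and are not tuned thereafter.  Two features matter:

* **Saturation ordering** (optical earliest, radar later, elevation
  nearly linear) is what makes additional roles add information and
  produces the monotone accuracy gain L → L+A → L+A+S.
* **Spatially correlated noise** is what keeps texture honest.  With
  white band noise, Gaussian texture layers average ~50 independent
  errors and become nearly noise-free predictors of the smooth height
  field, driving R² → 1 and erasing the tail bias — a regime no real
  stack exhibits, since moisture, albedo and speckle effects correlate
  over neighbouring pixels.

What the generator does *not* emulate: sensor physics (multiplicative
speckle, incidence-angle and moisture dependencies), fine-scale height
variation below the pixel grid, land-cover heterogeneity, geolocation
error, and any particular site's variogram.  Passing benchmarks on this
landscape therefore demonstrates the *mechanisms* (information content
of layers, tail-bias correction, variogram flattening by texture), not
site-specific accuracy; the real-data table values are not reproduced
numerically.

## Evaluation machinery

* Monte Carlo CV: repeated random subsampling with disjoint train/test
  splits per repetition ("rest" uses all remaining pixels); metrics are
  reported as mean ± sd across repetitions (sd, not standard error,
  ddof = 1; NaN-aware for tail subsets).  Default 25 repetitions; the
  benchmark tables use 400 training samples and test on the rest.
* Semi-variogram: `γ(h) = Σ_pairs (z_i−z_j)² / (2N(h))` with pairs
  binned by Euclidean pixel-center distance; default 30 equal-width
  bins to half the scene diagonal.  Raster variograms subsample valid
  pixels (default 3,000) to keep the pair count tractable; empty bins
  are NaN.  Variogram *model* fitting (sills/ranges, kriging) is out of
  scope — the variograms are descriptive diagnostics.

## Reproducibility and problem sizes

Every stochastic step (field generation, sampling, splits, forests,
background subsampling) derives from explicit seeds via
`numpy.random.SeedSequence` spawning, so one top-level seed fixes every
table bit-for-bit.  The shipped benchmarks use: simulation n = 10,000
with 5 repetitions; layer tables with 400 training pixels and ~32,000
test pixels per repetition; sample-size sweeps over 40–1,600 training
pixels against 5,000 test pixels; variograms on 2,500-pixel subsamples.
These sizes make the full benchmark suite run in minutes on a single
CPU while keeping CV spreads small enough to resolve the documented
orderings.

## Known limitations

* The MaxEnt feature set (linear + quadratic) cannot represent
  multimodal class densities; with very wide bins or heavily skewed
  training sets the density-ratio fit degrades before the forest does.
* RFBC's reflection assumes the bias stage can *learn* the primary
  stage's bias from the same predictors; when predictor noise is
  comparable to the signal (the 80 % scenario, or heavily saturated
  bands), part of the tail bias is information-theoretically
  irreducible and remains after correction.
* The landscape's rank-mapped uniform height histogram is a stylized
  choice; real height distributions are skewed, which changes tail
  sample sizes (and hence MSD1/MSD2 variance) but not the mechanisms.
* Classes emptied by small training samples are dropped (prior 0), so
  ME predictions cannot exceed the range of *observed* class centers —
  an inherent truncation shared by the expectation formula itself.
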