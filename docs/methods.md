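# Methods

## Scope

`wheatcgi` implements a complete quadrat-level growth-monitoring pipeline:
synthetic field campaign → radiometric calibration → spectral and textural
features → composite growth indices → regression inversion and evaluation.
This note documents the models, the parameters that matter, the synthetic
data design, the numerical choices, and what the tests do and do not show.

## Composite growth indices

Three ground indicators per quadrat — above-ground biomass (AGB, g of dry
mass per 1 m² quadrat), SPAD chlorophyll reading (unitless, 0–80) and leaf
water content (LWC = (FW − DW)/FW, a fraction) — are treated as
benefit-oriented (more is better) and min–max normalized column-wise across
the campaign. A constant column is rejected rather than silently zeroed,
because its entropy weight is undefined.

**Entropy weights.** Each normalized column is converted to proportions and
its Shannon entropy computed with normalization constant k = 1/ln m, where m
is the number of quadrats (with m quadrats, entropy of a column is at most
ln m, so e_i ∈ [0, 1]). Weights are w_i = (1 − e_i)/Σ(1 − e_i): an indicator
that varies sharply across quadrats (low entropy) earns a high weight, a
near-uniform one earns ~0. `CGI_ewm` is the weighted sum of the normalized
indicators, in [0, 1], higher = better.

**Fuzzy comprehensive evaluation.** The unit interval of each normalized
indicator is covered by five trapezoidal levels (poor → good). The knots are
the unique sum-to-one construction consistent with boundary centers at
0.2/0.4/0.6/0.8, a transition width of 0.1 centered on each boundary, and
head/tail plateaus ending at 0.15 and 0.85: level 1 has plateau [0, 0.15]
and ramp [0.15, 0.25]; interior levels have plateaus of width 0.1 and
complementary linear ramps; level 5 plateaus on [0.85, 1]. The memberships
form an exact partition of unity, so each row of the 3×5 matrix R sums
to 1. Aggregation uses the entropy weights, B = W·R, and defuzzification the
score vector F = [100, 75, 50, 25, 0]: `CGI_fce` = B·Fᵀ ∈ [0, 100]. Level 5
(best growth) maps to score 0, so `CGI_fce` falls as growth improves while
`CGI_ewm` rises — the two indices are anti-correlated by construction, and
the suite asserts Spearman ≤ 0 on every campaign.

Orientation is the one consistent with well-growing quadrats scoring 0:
higher normalized indicators reach higher levels, and higher levels carry
lower scores.

## Image features

**Calibration** is a single-point empirical line through the origin:
reflectance = DN / panel_DN × panel_reflectance, clipped to [0, 1]; the
panel mean DN may be global or per band. ROI windows are half-open,
0-based: an even window of size s around center r spans [r − s/2, r + s/2).

**Vegetation indices** are computed from band means exactly as defined in
`features.compute_vis` (docstring lists all twelve formulas). Two
definitions follow the source convention rather than the wider literature:
EVI2 = (NIR − R)/(1 + NIR + 2.4 R) (no 2.5 scale factor) and
MVI = (NIR − R)/√(NIR + R + 0.5). Vanishing denominators yield NaN for that
index instead of raising, so one degenerate quadrat cannot abort a batch.

**Textures.** Each of the red and green bands is min–max rescaled to 8 bits,
reduced to 32 gray levels, and its co-occurrence matrix accumulated at
distance 1 over the four unit directions, symmetrically, each direction
normalized then averaged (Σ P = 1 always). The counting is delegated to
`skimage.feature.graycomatrix`; the eight statistics (mean, variance,
contrast, dissimilarity, homogeneity, entropy, second moment, correlation)
are evaluated in-package from the averaged matrix and verified against a
brute-force pair-enumeration oracle. Correlation of a constant image is
defined as 0. The GLCM is computed once per 18×18 quadrat window (not as a
sliding-window texture image), since the regression consumes one scalar per
feature per quadrat.

## Regressors

* **PLS** — scikit-learn `PLSRegression`, 3 latent components by default,
  capped with a warning at the feasible maximum.
* **RF** — scikit-learn `RandomForestRegressor`, 100 trees, minimum leaf 5.
* **ELM** — features min–max scaled to [−1, 1] with training ranges; input
  weights and biases drawn uniformly on [−1, 1] from a seed; hidden layer
  H = sigmoid(XW + b) with 5 neurons; output weights via the exact
  pseudoinverse (so training predictions are the least-squares optimum for
  the drawn hidden layer, and interpolation is exact when the hidden count
  matches the sample count).
* **PSO-ELM** — a particle swarm (40 particles, 100 iterations,
  accelerations c₁ = 2.8, c₂ = 1.3, inertia decaying linearly 0.9 → 0.4,
  velocities and positions clamped to [−1, 1]) searches the concatenated
  input weights and biases; a particle's fitness is its training RMSE after
  solving the output weights for its hidden layer. The best-so-far trace is
  nonincreasing by construction.

Numerical choice: inside the swarm (fitness and final solve) the output
weights use a Tikhonov-stabilized solve with λ = 10⁻⁴·σ_max². An
unregularized swarm reliably discovers near-singular hidden layers
(σ_min/σ_max ≈ 10⁻³) whose huge output weights fit the training set through
delicate cancellation and explode on validation data (validation R² below
−20 was observed); the relative ridge caps that variance while perturbing
well-conditioned solves negligibly. The plain ELM keeps the exact
pseudoinverse.

## Evaluation protocol

Features enter a group only if their Pearson correlation with **both**
indices is significant at α = 0.01 (two-sided t test); an empty selection
falls back to the full pool with a warning. A single random 40/14 holdout
split (seeded, recorded in the report) is shared by all 24 grid cells
(3 feature groups × 2 indices × 4 models). Metrics are R² = 1 − SSres/SStot
and nRMSE = RMSE/ȳ × 100 %. The report also tabulates the relative R²
improvement of the combined feature group over vegetation indices alone,
100·(R²₃ − R²₁)/|R²₁|.

## Synthetic campaign design

The generator fabricates the statistical skeleton the analysis assumes; its
defaults are the package's study conditions.

* **Latent growth** g ∈ [0, 1]: a planar gradient across the quadrat grid
  (strength 0.8) plus U(−0.1, 0.1) jitter, clipped — emulating a field with
  a systematic subsidence gradient.
* **Ground links**: AGB = 50 + 400 g (± 9), SPAD = 25 + 30 g (± 1.2),
  LWC = 0.55 + 0.25 g (± 0.015), clipped to physical ranges; dry leaf weight
  DW = 2 + 3 g and FW back-solved so LWC = (FW − DW)/FW holds exactly.
  Noise-to-slope ratios are ordered AGB < SPAD < LWC so correlation analyses
  recover the biomass-first ordering. The absolute levels were fixed once so
  that validation accuracy of the inversion grid sits in the regime typical
  of UAV growth-index studies (R² roughly 0.5–0.8 at default noise).
* **Spectral response**: per-band mean reflectance follows a saturating
  Beer–Lambert-style soil→vegetation mixing curve, reflectance(g) = soil +
  (veg − soil)(1 − e^{−kg})/(1 − e^{−k}), with red extinguishing fastest
  (k = 6, 0.30 → 0.07) and NIR most linear (k = 2, 0.25 → 0.60). Red-based
  indices therefore flatten at high growth — the saturation that motivates
  texture features.
* **Spectral noise**: one per-quadrat, per-band offset (sd 0.03 by default)
  models soil-background and stand heterogeneity that band averaging cannot
  remove; per-pixel sensor noise at a third of that sd mostly averages out.
  Min–max quantization makes the texture statistics invariant to the
  quadrat-level offset, reproducing texture's robustness to background
  effects.
* **Texture**: each patch is a Gaussian random field smoothed with
  correlation length 0.4 + 1.4 g pixels, normalized and applied as ±25 %
  relative modulation of the band mean — canopy closure coarsens the spatial
  grain, so co-occurrence statistics carry growth signal in both bands.
* **Digital numbers**: DN = round(reflectance / 0.99 × 50000), clipped to
  16 bits, so the calibration step can be exercised end to end (the default
  experiment recalibrates from the DN patches).

What the generator does **not** emulate: radiative transfer, row/plant
geometry, spatially correlated soil maps, multi-date phenology, geometric
distortion and mosaicking artifacts, or view/illumination effects. Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes — monotone spectral/textural links degraded by background noise —
not that any accuracy level transfers to real fields.

## Problem sizes and determinism

All stochastic components (generator, splits, ELM draws, swarm) are driven
by explicit seeds; identical seeds give bit-identical outputs. The test
suite runs the full 24-cell grid over 20 matched campaigns for the ordering
checks and 5 campaigns for noise-free recovery; these sizes give stable
medians while keeping the suite under a minute on one CPU.

## Known limitations

* The entropy weights depend on the campaign's empirical spread, so the
  published weight vector is reproduced only as a fixture, not re-derived.
* The fuzzy score is piecewise linear with plateaus; as a regression target
  it is locally uninformative inside plateaus, which caps noise-free R²
  slightly below 1 for smooth regressors.
* The ELM's accuracy with 5 hidden neurons degrades as uninformative input
  dimensions are added (random projections mix noise into every unit); the
  swarm-optimized variant largely repairs this.
* A single 40/14 holdout (as in the emulated protocol) has high variance at
  n = 54; cross-validation would be preferable in production use.
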