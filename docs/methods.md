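# Methods

This note records the models implemented in `faceimprint`, the defaults
and why they were chosen, the numerical details, and the limits of what
the synthetic experiments demonstrate.

## Data model

A dataset is a stack of n images with pixel intensities in [0, 1] paired
with an n × m binary attribute table and an individual identifier per
row. Attributes are constant within an individual (each person answers
once; their several photos share the answers), so per-image variation
comes only from pixel noise. Intensities live in [0, 1] independent of
storage depth; PNGs are written at 8 or 16 bits (16 by default) and the
round-trip error is bounded by 1/(2^depth − 1). A JSON manifest records
the generating configuration, bit depth, face-oval geometry and a content
hash, so any dataset can be regenerated bit-identically from the manifest
alone.

## Synthetic generator

The generator emulates the structure the analysis assumes, not
photorealism:

- **Individuals and images.** Defaults of 969 individuals × 3 images at
  224×224 mirror the reference study design; every size is configurable,
  and the test suite runs at 16–32 pixels where ground truth is equally
  exact but hundreds of times cheaper.
- **Correlated attributes.** Each individual draws latent factors
  f ~ N(0, I_L) (L = 20 by default); attribute j is the indicator of
  loadingsⱼ·f + e > threshold with e ~ N(0, 0.5²) and loadings
  N(0, 1/L). This probit factor model reproduces a rich correlation
  structure with few knobs. Thresholds are drawn U(−0.8, 0.8) so
  prevalences vary realistically around one half. A column that comes
  out constant has its threshold reset to the median latent score
  (deterministic; both classes then occur), unless a degenerate fixture
  is explicitly requested.
- **Imprints.** The intercept image is a smooth face-like oval on a dark
  background, exactly mirror-symmetric. The first `n_active` attributes
  receive compact, horizontally symmetric Gaussian-blob imprints with
  amplitude drawn per attribute from effect_scale · U(0.25, 1) and random
  sign (heterogeneous effect sizes: some attributes are strongly
  imprinted, some weakly); the rest are exactly zero. The default
  effect_scale = 0.25 puts typical imprints at 6–25% of the intensity
  range — visible but noise-comparable, like real demographic signals.
  Optionally one attribute instead carries a low-amplitude,
  high-frequency, mirror-symmetric checker spanning the image, a stand-in
  for brand-specific camera-sensor fingerprints.
- **Rendering.** X_i = clip(P₀ + Σ P_j y_ij + ε, 0, 1) with
  ε ~ N(0, σ²) i.i.d. per pixel, σ = 0.05 by default. Gaussian pixel
  noise is a modeling choice — the noise of real selfies (JPEG artifacts,
  lighting, pose) is not characterized here. Everything is seeded; a
  single global seed fans out to per-stage seeds by CRC32 of
  "seed:stage", so stages are reproducible and independent.

What passing tests on this generator shows: the pipeline's statistics
(grouped CV, AUC, BH, Welch), its leakage guards, and the decomposition's
recovery behavior are correct under the assumed additive model. What it
does not show: performance on real photographs, where signals are
non-additive, pose- and lighting-confounded, and features come from deep
networks rather than pixel PCA.

## Features

Basic face metrics are computed over an ellipse (the face oval): per-image
R/G/B means inside the oval (a grayscale image duplicates its channel),
face width and height (twice the oval semi-axes) and their ratio (fWHR).
Additional named metrics can be registered, to a cap of 11 per image.
The oval comes from the dataset manifest, or is supplied by the user for
external images; landmark detection is out of scope.

Embedding backends replace pretrained networks: pixel PCA (SVD of
centered flattened pixels), a seeded Gaussian random projection, or
externally supplied per-image vectors for users who have real CNN
features. Blocks are concatenated and reduced by truncated SVD (columns
centered on training rows; the paper-scale default is 500 output
columns). **Everything with state is fitted on training rows only** and
then applied to all rows; a dedicated test certifies that including test
rows in the fit would change test features, i.e. that the guard is load-
bearing. SVD component signs are fixed (largest-magnitude entry positive)
for determinism.

## Prediction

One Bayesian ridge regression per attribute (scikit-learn's evidence-
maximization implementation; tolerance 1e−3, at most 300 update
iterations) on the chosen input set, treated as a linear probability
model. Scores are raw X·w + b: AUC is rank-based, so no calibration or
clipping is applied. A constant training target yields an intercept-only
model. Attributes that serve as demographic inputs are excluded from the
target list. Evidence maximization makes scores invariant to joint affine
transformations of the features and shrinks pure-noise fits toward zero;
both properties are tested.

## Evaluation

- **CV plan.** Per repeat, individuals (not images) are randomly
  partitioned into near-equal folds (sizes differ by ≤ 1); folds are not
  class-stratified. Defaults 20 × 5 give 100 cells.
- **AUC** is computed by the Mann–Whitney midrank identity; ties count
  one half. A fold where a variable has one class only is recorded as
  undefined and excluded, shrinking that variable's k rather than
  imputing a value.
- **Summary.** mean and SE = sd/√k over the defined measures;
  p = Φ((0.5 − mean)/SE), clamped to (0, 1); mean exactly 0.5 gives
  p = 0.5. The SE carries no correction for correlation between CV
  cells — cross-validation variance estimators are biased, and the
  resulting "significance" should be read with that caveat.
- **Selection.** BH(q) step-up over all variables with a defined p
  (cutoff = largest sorted p_(i) ≤ i·q/m; expected false positives
  reported as q × rejections), and the stricter-boundary 2SE criterion
  mean − 2·SE > 0.5 (strict inequality at the boundary). Whenever the BH
  cutoff is below Φ(−2) ≈ 0.023, the BH set is contained in the 2SE set.
- **Nested comparisons.** Counts of significant variables per input set
  with percent increases over the demographics-only reference, and
  one-sided Welch t-tests (unequal variances, Satterthwaite df) on the
  per-cell AUCs of a variable between two input sets. Zero-variance
  degenerate pairs resolve by sign convention (p = 0, 1, or 0.5).

## Occlusion maps

Grid cells (default 8×8; any divisor of the image size is allowed) are
masked in held-out images only, after the pipeline has been fitted on
full training images, and the per-cell mean AUC decrease is averaged over
CV cells. The default fill is the training-set mean pixel value per
location — the least out-of-distribution choice — with per-image-mean and
zero fills selectable. Pixel-based backends are required, since masking
must propagate into the features. The probe cannot localize redundantly
encoded signals; a test plants the same imprint in two distant cells and
verifies that neither mask alone collapses the AUC.

## Imprint decomposition

The objective is exactly

(1/n) Σ_i ‖X_i − P₀ − Σ_j P_j y_ij‖²_F + λ Σ_{j=0..m} 1ᵀ|P_j|1

on raw [0, 1] intensities and binary y, with λ = 0.01 by default and the
penalty index running from j = 0: the intercept **is** penalized, as the
objective states; `exclude_intercept_penalty` (off by default) relaxes
that. RGB input is converted to grayscale first (BT.601 weights) — color
information is deliberately lost, which bounds how much of predictability
prominence can explain.

Numerics:

- **Separability.** The problem is an independent lasso per pixel on the
  design [1, Y]; under the symmetry restriction, each mirrored pixel pair
  (column c ↔ column W−1−c, 0-based; even width required) becomes one
  doubled-sample lasso with doubled penalty. `lasso_pixel_oracle` solves
  these subproblems by coordinate descent to ~1e−12 tolerance and serves
  as the independent optimum on small instances.
- **Solvers.** OWL-QN (pseudo-gradient, L-BFGS two-loop with memory 10,
  orthant projection, backtracking Armijo line search) and FISTA with
  adaptive restart at step 1/L, L = (2a/n)·λ_max(ZᵀZ) (a = 2 under
  symmetry). Both start from all zeros — the problem is convex, so
  initialization affects only iteration count — and both are required by
  tests to match the oracle's objective within 1e−6 relative and its
  coefficients within 1e−3 on instances up to 32×32.
- **Stopping.** Training stops when 10 successive iterations fail to
  improve the best loss by a relative 1e−9, on a pseudo-gradient
  sup-norm below tolerance, or at `max_iter`. A non-finite loss aborts
  with the iteration number. Iteration counts are hardware- and
  data-dependent and are not asserted anywhere.
- **Diagnostics.** v_j = Σ|P_j| (prominence; zero iff the imprint is the
  zero matrix), Pearson correlation of v with mean hold-out AUC (with
  r²), and P_j / max|P_j| normalization for display (mid-gray = 0 in the
  written PNGs).

Monotonicity of total prominence in λ, exact halving of the free
parameter count under symmetry, and the dominance of the fitted symmetric
solution over the symmetrized unconstrained solution are all covered by
tests. With noise σ ≤ 0.02, imprint amplitudes ≥ 0.1, and ≥ 200 training
images, the active-attribute support is recovered with precision and
recall ≥ 0.9 at λ = 0.01, and noiseless fits at λ = 1e−4 recover imprint
shapes with pixel correlation ≥ 0.95.

## Problem sizes

The test suite and examples run on 16–32-pixel images with tens to a few
hundred individuals — sizes chosen so the full suite exercises every code
path, including the 300-individual, 50-attribute end-to-end megastudy, in
a few minutes on one CPU. All statistical properties checked are
scale-free; paper-scale runs (969 × 3 images at 224×224, 349 attributes)
use identical code paths and are configured the same way.

## Known limitations

- The linear probability model and the additive imprint model ignore
  interactions; a visual effect expressed only when attributes co-occur
  is attributed to neither.
- CV-based SEs are biased (cells share data); p-values are approximate.
- Occlusion misses redundant signals; prominence misses color-borne and
  nonlinear signals — on real data both are known to explain only part
  of predictability.
- The generator's Gaussian pixel noise and rigid geometry (fixed oval,
  no pose/lighting variation) make the synthetic task easier than real
  face analysis; absolute AUC levels here do not transfer to photographs.
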