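# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Patch sampling

Patches are squares of side √0.16 mm = 400 µm (side_px =
round(1000·√area/mpp); 200 px at the default 2 µm/px). Only the physical
area is fixed by convention; squares are the natural CNN input shape.
Coordinates are 0-based (row, col) with half-open footprints
[r0, r0+side) × [c0, c0+side). Sampling is uniform over all top-left
corners whose full footprint carries the dermis label — strict containment:
a patch touching one epidermis/subcutis/background pixel is invalid.
Centers are drawn with replacement, so overlap is allowed; this guarantees
feasibility on small biopsies and matches common random-patch practice.
Validity is precomputed with an integral image; candidates are then drawn
by rejection with a cap of 1000 candidates per requested patch. No valid
position at all raises a no-dermis error; hitting the cap on a fragmented
dermis raises a sampling-exhausted error that reports how many patches were
placed. Rejection (rather than enumeration) keeps the accepted distribution
exactly uniform over valid positions, which the chi-square uniformity test
verifies on a rectangular dermis.

## Feature backends

**texture32** is the deterministic default for all statistical work. Its 32
features, in fixed order: per-stain concentration statistics (mean, sd,
q10/q50/q90 for collagen, red counterstain, hematoxylin) after
optical-density stain separation with a fixed Masson-trichrome matrix;
collagen area fraction above an OD threshold of 0.25; per-RGB-channel
gradient-magnitude mean and sd; GLCM contrast/homogeneity/energy/correlation
at directed offsets (0,1) and (1,0) on a 16-level gray quantization
(normalized, unsymmetrized co-occurrence — the four statistics are
transpose-invariant, so offset orientation sign is immaterial); and
bright-object fraction plus connected components per 10⁴ px. The GLCM block
is verified against a brute-force O(N²) co-occurrence tally.

**cnn4096** is a numpy implementation of the AlexNet stack (5 conv + 3
max-pool + fc6/fc7) via im2col matrix multiplication. The reported feature
is the post-ReLU activation of a 4096-unit fully-connected layer;
AlexNet has two such layers and the choice is configurable (`fc6`|`fc7`,
default `fc7`). Preprocessing is bilinear resize to 227×227, [0,1] scaling,
and the standard ImageNet channel normalization. Without a pretrained ONNX
file the weights are He-initialized from a seed: the backend is then
shape-true and fully deterministic, which is what the pipeline contracts
need; its features are not semantically meaningful, so every statistical
test and the score-recovery benchmark use texture32. Local response
normalization is omitted (it affects values, not shapes, and only the
random-weight mode runs without onnxruntime).

## Fibrosis model

Training rows are patches with the biopsy's mRSS replicated; the fit
minimizes ½·MSE + λ·Σ|β| (scikit-learn's lasso objective with α = λ) with
an unpenalized intercept, coordinate-descent tolerance 1e-7, and a cap of
10,000 sweeps. λ = 0 is routed to ordinary least squares. Features are
standardized on the training rows only; held-out patches reuse the training
means/sds (no leakage). Constant features are dropped with a warning and
their coefficients fixed at 0.

λ selection minimizes the mean held-out squared error of *biopsy-level*
scores (patch predictions averaged before the error), over
leave-one-patient-out folds, or 10 seeded grouped folds when there are more
than 10 patients. Ties within 1e-12 go to the larger (more parsimonious) λ.
Fold disjointness by patient is asserted programmatically inside the
selector. After selection the final model is refit on all biopsies at λ*;
this refit-on-all convention is a deliberate choice and is recorded in the
model metadata. The Fibrosis Score is reported unclipped even though it
approximates the 0–51 mRSS scale through the intercept.

## Statistics layer

* **Cohen's κ** — unweighted, from the cross-tabulation; p_e from marginal
  products. Both-raters-constant is a typed degenerate-agreement error.
  Band cutpoints: ≤0 none, 0.01–0.20 none-to-slight, 0.21–0.40 fair,
  0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect;
  the open gap (0, 0.01) is assigned to "none to slight". For the
  16-parameter table, continuous measurements (µm, counts, percent) are
  quintile-binned on the pooled two-rater values before κ; binary and 0–5
  ordinal scores are compared as-is.
* **Proportional odds** — cumulative-logit MLE, Newton-Raphson with
  analytic gradient and Hessian, step-halving to keep the likelihood
  ascending and the cutpoints ordered, convergence at gradient ∞-norm
  < 1e-8. Sign convention: P(Y ≤ k|x) = logistic(θ_k − βx), so OR = e^β > 1
  means larger x favors higher categories. |β| or |θ| exceeding 30 raises a
  separation error rather than returning a meaningless estimate. Inference
  is Wald (observed information); no profile likelihood. K = 2 reduces
  exactly to binary logistic regression (tested against an independent
  logistic MLE to 1e-6, and against statsmodels' ordinal fit for K = 6).
* **OR table** — one fit per parameter against a per-biopsy predictor
  (mRSS or Fibrosis Score), consensus across raters/sessions: majority
  vote (binary), rounded mean (ordinal), mean rounded to integer on the
  reported scale (continuous — the integer binning under which they enter
  the ordinal fit). α = 0.05, no multiplicity correction (the analysis is
  exploratory by design). Parameters whose fit fails a precondition are
  reported NA with the reason.
* **Per-week slopes** — random-intercept + random-slope model with
  *independent* (diagonal) random-effect covariance, REML via statsmodels
  MixedLM with the off-diagonal covariance constrained to zero. Negative
  variance estimates are clamped at 0 in the report. β1's p-value is Wald.
* **Spearman** — average-rank Pearson (scipy), t-approximation p with
  n−2 df; an exact-permutation p is available for n ≤ 8.

## Synthetic data: what it emulates and what it does not

The slide renderer is deliberately stylized: a white background margin, a
thin epidermis strip, a dermis band with oriented band-pass fiber texture,
sparse dark nuclei, ring-shaped vessel profiles, and a subcutis band with
white fat vacuoles, all colored through a fixed Beer–Lambert stain model so
stain separation recovers planted concentrations. The one property the
pipeline's tests rely on is the monotone severity→texture link: the dermal
collagen fraction is 0.2 + 0.5·severity (plus a small seed-only jitter),
realized exactly by quantile thresholding of the fiber field, hence
monotone in severity at fixed seed. Defaults: mpp = 2.0 µm/px and
2048×3072 px, so one 0.16 mm² patch is 200×200 px and 100 patches fit
comfortably at desk-scale runtimes.

Cohorts draw baseline mRSS uniformly on the 15–40 eligibility band, with a
per-patient linear drift (default mean −0.04, sd 0.05 mRSS/week,
visit noise sd 1 point — i.e. roughly the −2-point median 52-week change
seen in early diffuse disease) and visits at weeks 0/24/52. The latent
severity is the linear map (mRSS − 15)/25 clipped to [0, 1]; any monotone
link suffices for recovery testing, and this one keeps the score scale
interpretable.

Rater simulation derives 16 true scores from the planted truth through
fixed monotone thresholds (documented in `synthetic/raters.py`, e.g.
subcutaneous fat loss true iff severity > 0.5, telangiectasia true iff ≥ 8
ectatic vessel profiles) and corrupts them per rater: binary flips, ±1
ordinal jitter, multiplicative continuous noise, plus extra drift on the
second session (emulating re-scoring after a washout). Because the
truth→score links are nearly deterministic, consensus scores at the default
cohort size can be perfectly separated by the predictor; the ordinal fits
then correctly refuse (separation error → NA rows). The OR-recovery
benchmark therefore uses the proportional-odds simulator, which generates
genuinely stochastic ordinal outcomes at planted effect sizes.

What passing tests do **not** show: performance on real trichrome sections
(stain variability, batch effects, fixation artifacts, non-band tissue
geometry, real scanner optics), dermis segmentation (masks are required
inputs; their delineation on real slides is out of scope), or semantic
validity of CNN features (random weights are shape-true only).

## Problem sizes and determinism

Default test and benchmark sizes: 20 patients × 3 visits (60 biopsies),
100 patches/biopsy, texture32 (D = 32); proportional-odds simulations at
n = 5000; LMM recovery at 200 patients × 3 visits; the full pipeline run
takes a few minutes on one core. One global seed fans out to per-stage
child seeds through a fixed `SeedSequence` derivation; a rerun with the
same config reproduces every output hash.

## Known limitations

* The lasso solver, OLS, mixed model and Spearman machinery are delegated
  to scikit-learn/statsmodels/scipy; only the proportional-odds estimator,
  kappa, patch sampling, the renderer and the score aggregation are
  in-package. The delegated pieces are pinned by oracle tests.
* Wald inference everywhere; small-sample ordinal ORs can be overestimated
  and separation is common at n ≲ 100 with strong effects.
* The cnn4096 ONNX path requires onnxruntime and pretrained weights, and is
  untested beyond its loading contract in environments without them.
* Local arm skin score is not modeled; training targets are total mRSS
  only. Elastic-net/ridge variants are out of scope.
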