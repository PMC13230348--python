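# Methods

## Scope and model of the data

`synthmetrics` evaluates a generative model of 2D grayscale medical images
by comparing a *real* set and a *synthetic* set in an embedding space. The
package takes no position on the embedder: any deterministic map from one
image to a fixed-length vector fits the extractor contract. At desk scale
the bundled extractors are pixel flattening and a seeded Gaussian random
projection; pretrained CNN embedders (Inception V3, VGG-16) can be adapted
behind the same contract but are deliberately not bundled — no weights ship
with the package, and nothing downstream depends on which embedder is used.

## Preprocessing chain

Registered 3D volumes are reduced to one 2D slice per subject:

1. per-volume min–max normalization to [0,1] (a constant volume is a
   degenerate input and is rejected, not silently mapped);
2. central axial slice at 0-based index ⌊Z/2⌋ — the upper middle slice for
   even Z. The convention is a package choice: "central" is ambiguous for
   even axes, and ⌊Z/2⌋ is deterministic and configurable via `axis`;
3. centered zero-padding to a square canvas, top/left margin = ⌊pad/2⌋.
   Padding never crops; original pixels are embedded bit-exactly;
4. stacking into a single NIfTI-1 file, slices along the third axis,
   identity affine, float32 — chosen so write→read round trips are
   bit-identical.

## Metrics

### Fréchet distance (FID)

Computed between sample moments (covariance divisor n−1). The cross term
Tr((Σ_r Σ_s)^{1/2}) is evaluated via the symmetric eigendecomposition of
Σ_r^{1/2} Σ_s Σ_r^{1/2}, which is stable and manifestly symmetric in its
arguments. Eigenvalues below −10⁻⁶·(Tr Σ_r + Tr Σ_s) raise (the inputs are
not PSD); smaller negative values are numerical noise and are clipped to
zero, so the score is always ≥ 0.

### Kernel distance (KID)

Unbiased MMD² with kernel k(u,v) = (uᵀv·s + c)^p, defaults p = 3, s = 1/d,
c = 1 (the standard cubic choice). The estimator averages over `n_subsets`
(default 100) random subsets of `subset_size` (default min(n, 1000))
samples drawn without replacement from each side, seeded; the mean and the
across-subset standard deviation are both reported. When the subset covers
the whole set the estimate is exact and the dispersion is zero. Note the
estimator is unbiased, so small negative values are expected near zero.

### k-NN manifold metrics

Radii are exact k-th-nearest-neighbor distances (full pairwise distances,
chunked at 2048 rows; ties broken by smallest index via stable sort — exact
search only, since determinism matters more than speed at ≤ tens of
thousands of points). Sphere membership is **inclusive** (distance ≤
radius): duplicate points produce zero radii, and inclusive membership is
what makes "synthetic = real ⇒ all scores 1" hold exactly. Defaults k = 3
for precision/recall and k = 5 for density/coverage (the conventional
choices for these metric families); both are exposed in `EvalConfig`.

Geometric caveat: within one mode, the probability that a fresh same-density
point lands inside the union of k-NN spheres is not 1 — empirically ≈ 0.95
at k = 3 in 2D, degrading with dimension (≈ 0.89 at d = 8). Directional
claims ("recall falls to the retained-mode mass") are therefore sharpest on
planar well-separated fixtures; in high dimension every manifold score
carries a systematic deficit of several percent even for a perfect
generator.

### One-class hypersphere and α-precision / β-recall

The one-class transform is deterministic whitening: center at the mean of
the real embeddings, map x ↦ Σ̃^{-1/2}(x − μ) with Σ̃ = Σ + εI,
ε = 10⁻⁶·Tr(Σ)/d; radii are the resulting Euclidean norms
(Mahalanobis-style distances). This satisfies the one-class contract —
typical samples concentrate near the center, outliers sit near the
boundary — while being exactly reproducible and rotation-invariant. A
learned one-class objective can replace it behind the same `OneClassModel`
surface. Rank-deficient covariances (n ≤ d) fall back to the regularized
inverse with a warning; radii are then strongly shrunk and α/β values
should be interpreted with care.

α-precision: for each level α, P(α) = fraction of synthetic radii at most
the α-quantile (nearest-rank: the ⌈αn⌉-th order statistic; the quantile
convention is a declared choice) of real radii. β-recall swaps the roles.
The summary score is 1 − 2∫|P(α) − α|dα on the level grid (default 20
points, 0.05…1.00) *prepended with the origin at zero deviation*, by
trapezoid, clipped to [0,1]. The origin point makes the degenerate cases
exact: identical radius distributions score exactly 1, synthetic mass
entirely outside the real support scores exactly 0 (∫α dα = ½). Without it
the all-outside case would score 0.0025 on the default grid.

### Authenticity

Real sample i is *memorized* when min_j d(i, synth_j) < min_{i'≠i} d(i, i').
Both minima are computed; nothing is assumed from geometry. The arg-min
synthetic sample of each flagged real is the *memorizer*; memorizers are
deduplicated and the per-batch score is 1 − (#memorizers / batch size).
Synthetic samples are shuffled once (seeded) and split into disjoint
batches of size equal to the real count until the target count (default
50,000) or the synthetic set is exhausted; a final partial batch is kept
and weighted by its own size in the mean. Disjoint batches (rather than
resampling) are a declared choice — they make the score a function of a
single seeded partition.

Calibration note: for a generator that matches the real distribution
exactly, authenticity is *not* 1. With matched sizes, each real's nearest
neighbor is synthetic with probability ≈ n_s/(n_s + n_r − 1) ≈ ½ by
exchangeability, so the ideal-generator score sits near 0.5–0.65, not near
1. High authenticity (→ 1) indicates synthetic samples systematically
farther from reals than reals are from each other; 0 proves copying. The
score is a copying audit, not a calibration measure, and the test suite
asserts its extremes and its monotone response to copy jitter rather than
an "ideal ≈ 1" that the definition does not imply.

### Visual Turing test

Sessions are balanced (default 50/50), sampled and shuffled with one seed;
the presentation list carries no labels and the answer key is a separate
artifact, so observers are blinded by construction. Scoring uses the real
class as positive: accuracy (TP+TN)/total, sensitivity TP/(TP+FN),
specificity TN/(TN+FP). Display rounding is half-up to 2 decimals (matching
how such tables are conventionally printed); full-precision values are
always retained alongside. Zero denominators yield `None` rather than an
exception. The cosine k-NN audit uses exact cosine similarities with ties
broken by smaller synthetic index.

## Fixture generators (what a green test establishes)

`gen_feature_clouds` draws real features from a mixture of spherical
Gaussians and synthetic features from a perturbed copy with three
independent pathology dials: global mean shift (fidelity degradation), mode
dropping (diversity collapse; surviving weights renormalized), and jittered
copying of real samples (memorization). Defaults: two equal-weight modes
separated by 20 sd (well beyond the ≥ 6 sd that makes sphere-membership
geometry essentially exact), n = 500 per side, d = 8 (chosen as a
realistic low-dimensional stand-in for embedding space; geometric
acceptance checks use d = 2 where union-of-spheres expectations are
sharpest, see the caveat above). All draws come from one
`numpy.random.default_rng(seed)` stream (PCG64), so outputs are
bit-reproducible across platforms.

`gen_phantom_stack` produces elliptical pseudo-brain slices (seeded random
axes and orientation, lateral intensity gradient, multiplicative speckle)
in [0,1]. These fixtures exercise the image → embedding → metric path; they
do not emulate MRI physics (no k-space, tissue contrast, bias fields or
registration artifacts), so green tests establish the correctness and
sensitivity of the *metrics*, not any claim about real scanners or real
generative models.

## Protocols and reporting

`run_protocol` executes every metric under one `EvalConfig`: matched mode
subsamples the synthetic set to the real count (seeded, without
replacement), fixed mode caps it at a configured count; all randomness
(KID subsets, authenticity batches, subsampling) derives from the single
config seed, making reports bit-for-bit reproducible. Per-metric failures
are caught and recorded; the report is marked partial instead of aborting.
Scores are grouped fidelity / diversity / generalization with FID and KID
in a joint "fidelity+diversity (composite)" subgroup; reports serialize to
JSON (full provenance: config, versions, seeds, AUC definition), CSV and
Markdown with a fixed metric order.

## Known limitations

- Exact neighbor search is O(n²) memory-chunked; beyond ~10⁵ points an
  approximate index would be needed (out of scope).
- The whitening one-class transform is unimodal: for strongly multimodal
  real data its center can fall between modes, compressing the contrast of
  α-precision/β-recall (it remains a valid calibration comparison).
- Turing-test tooling covers session construction and scoring only; the
  image-viewing application and inter-observer agreement statistics are out
  of scope.
- No pretrained embedders ship with the package, so published
  Inception/VGG-based scores are not directly reproducible here; all
  quantitative checks run on the bundled fixture generators.
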