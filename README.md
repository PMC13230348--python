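# synthmetrics

Multi-dimensional evaluation of synthetic medical images. `synthmetrics` is
for researchers who train generative models (GANs, diffusion models) on
scarce medical imaging data — e.g. 2D brain-MRI slices — and need to answer
three distinct questions that no single score answers:

* **Fidelity** — are the synthetic images realistic?
* **Diversity** — do they cover the whole real data distribution, or has the
  generator mode-collapsed onto a subset?
* **Generalization** — are they novel, or memorized copies of training
  images (a privacy failure)?

## What it computes

All metrics operate on embedded images (any extractor satisfying a simple
contract; pixel-flatten and seeded random-projection extractors ship with
the package).

**Composite (fidelity + diversity).**
FID, the Fréchet (Wasserstein-2) distance between Gaussian fits
(μ_r, Σ_r), (μ_s, Σ_s) of the real and synthetic embeddings:

    FID = ‖μ_r − μ_s‖² + Tr(Σ_r + Σ_s − 2(Σ_r Σ_s)^{1/2})

and KID, the unbiased squared maximum mean discrepancy under the cubic
polynomial kernel k(u,v) = (uᵀv/d + 1)³, averaged over seeded subsets.

**Separated fidelity/diversity.** Precision, recall, density and coverage
from k-NN union-of-spheres manifold estimates: each point's sphere has
radius equal to the distance to its k-th nearest neighbor; precision is the
fraction of synthetic samples inside the real manifold, recall the reverse,
density the per-synthetic count of containing real spheres normalized by k,
and coverage the fraction of real spheres containing a synthetic sample.

**Outlier-robust + memorization.** α-precision, β-recall and authenticity
on a one-class hypersphere embedding (deterministic whitening: center =
mean of real embeddings, radii = regularized Mahalanobis distances).
α-precision asks whether the α-most-typical real region contains an
α-fraction of synthetic samples for every α, summarized as
1 − 2∫|P(α) − α|dα; β-recall swaps the roles. Authenticity flags a real
sample as *memorized* when a synthetic sample lies closer to it than any
other real sample, and reports the fraction of synthetic samples not
implicated, averaged over seeded disjoint batches.

**Perceptual evaluation.** Blinded visual Turing-test sessions (50 real +
50 synthetic in seeded random order, answer key held separately) scored as
accuracy / sensitivity / specificity with the real class positive, and a
cosine k-NN audit that ranks, per real image, the most similar synthetic
images for visual memorization review.

**Preprocessing.** NIfTI slice-stack I/O and the standard 2D chain:
per-volume [0,1] min–max normalization, central axial slice (index
⌊Z/2⌋), centered zero-padding to a square canvas, stacking to one
H×W×N volume.

## Worked example

```bash
python examples/evaluate_generator.py
```

scores a healthy and a mode-collapsed simulated generator against the same
two-mode real distribution (matched sample sizes, seed 0):

```
ideal generator:            mode-collapsed generator:
  fid                0.8523   fid              197.7203
  precision          0.9850   precision          0.9825
  density            0.9775   density            0.9425
  alpha_precision    0.9463   alpha_precision    0.7993
  recall             0.9675   recall             0.4475
  coverage           0.9675   coverage           0.4575
  beta_recall        0.9504   beta_recall        0.8056
```

The collapsed generator still looks perfect to the fidelity metrics (its
samples are all realistic) but recall and coverage fall to the retained-mode
mass of ≈0.5 and FID explodes — the signature of mode collapse that a
composite score alone would blur. The other example scripts
(`preprocess_slices.py`, `turing_test.py`, `memorization_audit.py`) walk
the preprocessing chain, reader-study scoring, and the memorization audit
the same way.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: it generates the
seeded fixture scenario and a phantom image stack, runs the full evaluation
protocol on both (feature path and image → embedding → metric path), and
prints every grouped metric.
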