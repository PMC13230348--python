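"""Outlier-robust fidelity/diversity and memorization metrics on the hypersphere.

alpha-precision and beta-recall evaluate precision/recall inside
quantile-thresholded "typical" regions of the one-class hypersphere: as the
typicality level alpha sweeps (0, 1], the alpha-ball (radius = alpha-quantile
of real radii) should contain exactly an alpha-fraction of synthetic samples
if the two radius distributions match.  Each curve is summarized as
1 - 2 * integral |P(alpha) - alpha| d alpha, so perfect calibration scores 1
and total mismatch scores 0.

Authenticity audits memorization: a real sample is *memorized* if some
synthetic sample lies closer to it than any other real sample does.  The
score is the fraction of synthetic samples not implicated as memorizers,
averaged over seeded disjoint batches of synthetic samples (each the size
of the real set) until a target synthetic count is covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import FeatureMatrix, HypersphereEmbedding

DEFAULT_GRID = np.round(np.linspace(0.05, 1.0, 20), 10)


@dataclass
class QuantileCurve:
    """A typicality sweep: score at each grid level plus the AUC summary."""

    grid: np.ndarray
    values: np.ndarray
    auc_score: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.grid.size == 0:
            raise ValueError("empty grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid[0] <= 0 or self.grid[-1] > 1:
            raise ValueError("grid values must lie in (0, 1]")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("curve values must lie in [0, 1]")


@dataclass
class AuthenticityResult:
    """Per-batch authenticity scores and their (size-weighted) mean."""

    per_batch_scores: list[float]
    batch_sizes: list[int]
    final: float

    @property
    def n_batches(self) -> int:
        return len(self.per_batch_scores)


def _nearest_rank_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: smallest value with at least ceil(q*n) mass."""
    n = sorted_values.size
    idx = int(np.ceil(q * n)) - 1
    return float(sorted_values[max(idx, 0)])


def _calibration_curve(
    reference_radii: np.ndarray, query_radii: np.ndarray, grid: np.ndarray
) -> QuantileCurve:
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty grid")
    ref_sorted = np.sort(reference_radii)
    values = np.empty(grid.size)
    for j, q in enumerate(grid):
        threshold = _nearest_rank_quantile(ref_sorted, q)
        values[j] = float((query_radii <= threshold).mean())
    # Deviation from the diagonal, integrated over (0, 1]. The origin is
    # prepended with zero deviation (both the ideal and observed fractions
    # vanish as the ball shrinks to the center), making the degenerate
    # endpoints exact: identical distributions -> 1, disjoint -> 0.
    alphas = np.concatenate(([0.0], grid))
    deviation = np.concatenate(([0.0], np.abs(values - grid)))
    auc = 1.0 - 2.0 * float(np.trapezoid(deviation, alphas))
    return QuantileCurve(grid=grid, values=values, auc_score=float(np.clip(auc, 0.0, 1.0)))


def alpha_precision(
    real_h: HypersphereEmbedding,
    synth_h: HypersphereEmbedding,
    grid: np.ndarray | None = None,
) -> QuantileCurve:
    """Fidelity inside typicality balls of the real distribution.

    For each alpha, P(alpha) is the fraction of synthetic samples whose
    hypersphere radius is at most the alpha-quantile (nearest-rank) of the
    real radii.  Both embeddings must come from the same one-class model.
    """
    grid = DEFAULT_GRID if grid is None else grid
    return _calibration_curve(real_h.radii, synth_h.radii, grid)


def beta_recall(
    real_h: HypersphereEmbedding,
    synth_h: HypersphereEmbedding,
    grid: np.ndarray | None = None,
) -> QuantileCurve:
    """Diversity: the role-swapped counterpart of alpha-precision.

    Thresholds come from the synthetic radii; membership is counted over the
    real samples.  Mode-collapsed generators (synthetic mass near the
    center) leave most real samples outside every beta-ball, scoring near 0.
    """
    grid = DEFAULT_GRID if grid is None else grid
    return _calibration_curve(synth_h.radii, real_h.radii, grid)


def flag_memorized(
    real: FeatureMatrix, synth_batch: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Identify memorized reals and the synthetic samples memorizing them.

    Real sample i is flagged iff its nearest synthetic sample is closer than
    its nearest other real sample.  Returns ``(real_flags, synth_flags)``
    boolean arrays; the arg-min synthetic sample of each flagged real is
    flagged as its memorizer (deduplicated).
    """
    if real.d != synth_batch.d:
        raise ValueError(f"dimension mismatch: {real.d} vs {synth_batch.d}")
    d_rr = cdist(real.values, real.values)
    np.fill_diagonal(d_rr, np.inf)
    nearest_real = d_rr.min(axis=1)
    d_rs = cdist(real.values, synth_batch.values)
    nearest_synth = d_rs.min(axis=1)
    real_flags = nearest_synth < nearest_real
    synth_flags = np.zeros(synth_batch.n, dtype=bool)
    if real_flags.any():
        synth_flags[np.unique(d_rs[real_flags].argmin(axis=1))] = True
    return real_flags, synth_flags


def authenticity(
    real: FeatureMatrix,
    synth: FeatureMatrix,
    target_count: int = 50_000,
    seed: int = 0,
) -> AuthenticityResult:
    """Fraction of synthetic samples not memorized from the real set.

    Synthetic samples are shuffled with ``seed`` and partitioned into
    disjoint batches of size equal to the real count, until ``target_count``
    synthetic samples are covered (or the synthetic set is exhausted).  A
    final partial batch is included and weighted by its own size.  Per batch,
    the score is 1 - (#flagged synthetic / batch size); the final value is
    the size-weighted mean.  Synthetic sets smaller than the real set fall
    back to a single batch with a warning.
    """
    if synth.n < real.n:
        warnings.warn(
            f"synthetic count {synth.n} < real count {real.n}; "
            "falling back to a single batch",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(synth.n)
    batch_size = min(real.n, synth.n)
    limit = min(target_count, synth.n)
    scores: list[float] = []
    sizes: list[int] = []
    start = 0
    while start < limit:
        idx = order[start : min(start + batch_size, limit)]
        batch = FeatureMatrix(
            synth.values[idx],
            source="synthetic",
            extractor_id=synth.extractor_id,
            sample_ids=[synth.sample_ids[i] for i in idx],
        )
        _, synth_flags = flag_memorized(real, batch)
        scores.append(1.0 - synth_flags.sum() / idx.size)
        sizes.append(int(idx.size))
        start += idx.size
    final = float(np.average(scores, weights=sizes))
    return AuthenticityResult(per_batch_scores=scores, batch_sizes=sizes, final=final)
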