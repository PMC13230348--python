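"""k-NN manifold metrics: precision, recall, density, coverage.

Each embedded point set is modeled as a union of spheres — one sphere per
point, with radius equal to the Euclidean distance to the point's k-th
nearest neighbor (self excluded).  Precision asks what fraction of
synthetic samples fall inside the real manifold (fidelity); recall swaps
the roles (diversity).  Density and coverage refine the pair against
outlier sensitivity: density counts, per synthetic sample, how many real
spheres contain it (normalized by k), and coverage counts the fraction of
real spheres containing at least one synthetic sample.

All searches are exact (full pairwise distances, chunked), with ties broken
by smallest index so results are deterministic across platforms.  Sphere
membership is inclusive (distance <= radius), so a synthetic set equal to
the real set always scores 1 even when duplicate points give zero radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import FeatureMatrix

_CHUNK = 2048  # rows per pairwise-distance block; caps memory at ~n*chunk*8 bytes


@dataclass
class ManifoldModel:
    """Point set plus per-point k-th-NN radii: a union-of-spheres support estimate."""

    points: np.ndarray
    k: int
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        if self.k >= self.points.shape[0]:
            raise ValueError("k must be smaller than the number of points")
        if np.any(self.radii < 0):
            raise ValueError("radii must be nonnegative")


def knn_radii(features: FeatureMatrix, k: int) -> ManifoldModel:
    """Distance from each point to its k-th nearest distinct-index point.

    Requires n > k >= 1.  Exact O(n^2) search; equidistant neighbors are
    ordered by index (stable sort), which only matters for exact ties.
    """
    x = features.values
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more points than neighbors: n={n}, k={k}")
    radii = np.empty(n)
    for start in range(0, n, _CHUNK):
        block = slice(start, min(start + _CHUNK, n))
        dist = cdist(x[block], x)
        rows = np.arange(block.start, block.stop)
        dist[rows - block.start, rows] = np.inf  # exclude self
        part = np.sort(dist, axis=1, kind="stable")
        radii[block] = part[:, k - 1]
    return ManifoldModel(points=x, k=k, radii=radii)


def _containment_counts(model: ManifoldModel, query: np.ndarray) -> np.ndarray:
    """For each query point, the number of model spheres that contain it."""
    counts = np.zeros(query.shape[0], dtype=np.int64)
    for start in range(0, query.shape[0], _CHUNK):
        block = slice(start, min(start + _CHUNK, query.shape[0]))
        dist = cdist(query[block], model.points)
        counts[block] = (dist <= model.radii[np.newaxis, :]).sum(axis=1)
    return counts


def _covered_flags(model: ManifoldModel, query: np.ndarray) -> np.ndarray:
    """For each model sphere, whether it contains at least one query point."""
    flags = np.zeros(model.points.shape[0], dtype=bool)
    for start in range(0, query.shape[0], _CHUNK):
        block = slice(start, min(start + _CHUNK, query.shape[0]))
        dist = cdist(query[block], model.points)
        flags |= (dist <= model.radii[np.newaxis, :]).any(axis=0)
    return flags


def precision(real_m: ManifoldModel, synth: FeatureMatrix) -> float:
    """Fraction of synthetic samples inside the real k-NN manifold (fidelity)."""
    counts = _containment_counts(real_m, synth.values)
    return float((counts > 0).mean())


def recall(real: FeatureMatrix, synth_m: ManifoldModel) -> float:
    """Fraction of real samples inside the synthetic k-NN manifold (diversity)."""
    counts = _containment_counts(synth_m, real.values)
    return float((counts > 0).mean())


def density(real_m: ManifoldModel, synth: FeatureMatrix) -> float:
    """Mean real-sphere membership count per synthetic sample, normalized by k.

    (1 / (k M)) * sum over synthetic samples of the number of real spheres
    containing them; unbounded above (a value > 1 means synthetic samples sit
    in denser regions than typical real neighbors).
    """
    counts = _containment_counts(real_m, synth.values)
    return float(counts.sum() / (real_m.k * synth.n))


def coverage(real_m: ManifoldModel, synth: FeatureMatrix) -> float:
    """Fraction of real spheres containing at least one synthetic sample.

    Spheres are built around the real data, which makes the score robust to
    synthetic outliers; sensitive to the synthetic sample count.
    """
    flags = _covered_flags(real_m, synth.values)
    return float(flags.mean())
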