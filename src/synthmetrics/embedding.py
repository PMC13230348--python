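"""Feature extraction contract and the one-class hypersphere transform.

All quantitative metrics operate on embedded images — an n x d
:class:`FeatureMatrix` produced by any extractor satisfying a minimal
contract (one image in, one fixed-length vector out, deterministic for a
fixed seed).  Two desk-scale extractors ship here: pixel flattening and a
seeded Gaussian random projection.  Pretrained CNN embedders (Inception,
VGG) plug in behind the same contract but are not bundled.

The outlier-robust metrics (alpha-precision, beta-recall, authenticity)
consume features mapped into a hypersphere in which typical samples sit
near the center and outliers near the boundary.  The default one-class
transform is deterministic whitening: center at the mean of the real
embeddings, radii as ridge-regularized Mahalanobis distances.  This
satisfies the one-class contract (mass concentrated near the center,
outliers pushed out) while being exactly reproducible; a learned one-class
objective can be substituted behind :class:`OneClassModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import SliceStack


@dataclass
class FeatureMatrix:
    """n x d real embedding matrix tagged with provenance.

    ``source`` is ``"real"`` or ``"synthetic"``; ``extractor_id`` names the
    embedder that produced the rows; ``sample_ids`` map rows back to images.
    """

    values: np.ndarray
    source: str = "real"
    extractor_id: str = "unknown"
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"expected an n x d matrix, got ndim={self.values.ndim}")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError(f"need n >= 1 and d >= 1, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values).all(axis=1))[0])
            raise ValueError(f"non-finite feature values at row {bad}")
        if self.source not in ("real", "synthetic"):
            raise ValueError(f"source must be 'real' or 'synthetic', got {self.source!r}")
        if not self.sample_ids:
            self.sample_ids = [f"{self.source}_{i:06d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("one sample id per row required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class HypersphereEmbedding:
    """One-class-mapped features with their center and per-sample radii.

    Invariant: ``radii[i]`` equals the Euclidean distance from ``mapped[i]``
    to ``center`` exactly (radii are derived, never free parameters).
    """

    mapped: np.ndarray
    center: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.mapped = np.asarray(self.mapped, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        if np.any(self.radii < 0):
            raise ValueError("radii must be nonnegative")
        expected = np.linalg.norm(self.mapped - self.center, axis=1)
        if not np.allclose(self.radii, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("radii inconsistent with mapped coordinates")


class FlattenExtractor:
    """Identity embedder: flattens each H x W slice to an H*W vector."""

    id = "flatten"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image, dtype=np.float64).ravel()


class RandomProjectionExtractor:
    """Seeded Gaussian random projection of flattened pixels to ``dim``.

    The projection matrix is drawn once at construction from
    ``default_rng(seed)`` and scaled by 1/sqrt(dim), so the same (seed, dim,
    input shape) always yields the same embedding.
    """

    def __init__(self, dim: int = 32, seed: int = 0):
        if dim < 1:
            raise ValueError("projection dimension must be >= 1")
        self.dim = dim
        self.seed = seed
        self.id = f"randproj_d{dim}_s{seed}"
        self._matrix: np.ndarray | None = None

    def __call__(self, image: np.ndarray) -> np.ndarray:
        flat = np.asarray(image, dtype=np.float64).ravel()
        if self._matrix is None or self._matrix.shape[0] != flat.size:
            rng = np.random.default_rng(self.seed)
            self._matrix = rng.standard_normal((flat.size, self.dim)) / np.sqrt(self.dim)
        return flat @ self._matrix


def embed(stack: SliceStack, extractor, source: str = "real") -> FeatureMatrix:
    """Embed every slice of a stack; row i is ``extractor(image i)``.

    Raises ``ValueError`` (with the offending slice index) if the extractor
    returns non-finite values.
    """
    rows = []
    for i in range(stack.n):
        vec = np.asarray(extractor(stack.images[:, :, i]), dtype=np.float64).ravel()
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"extractor returned non-finite values for slice {i}")
        rows.append(vec)
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError("extractor returned vectors of differing length")
    extractor_id = getattr(extractor, "id", extractor.__class__.__name__)
    return FeatureMatrix(
        np.vstack(rows), source=source, extractor_id=extractor_id,
        sample_ids=list(stack.labels),
    )


@dataclass
class OneClassModel:
    """Fitted whitening transform: x -> (x - mean) @ W with W = Sigma^{-1/2}.

    ``radii_fit`` are the radii of the fitting (real) samples, reproduced
    exactly when the fitting set is re-mapped.
    """

    mean: np.ndarray
    whitener: np.ndarray
    ridge: float
    radii_fit: np.ndarray

    @property
    def d(self) -> int:
        return self.mean.shape[0]


def fit_oc_transform(real: FeatureMatrix) -> OneClassModel:
    """Fit the default one-class transform on real embeddings.

    Centers at the sample mean and whitens with the inverse symmetric square
    root of the ridge-regularized covariance (ridge eps = 1e-6 * trace(Sigma)/d,
    applied always; a rank-deficient covariance additionally triggers a
    warning and a larger floor so the transform stays finite).  Radii of the
    mapped samples are Mahalanobis-style distances: typical samples small,
    outliers large; the mean of the mapped reals is the origin.
    """
    x = real.values
    n, d = x.shape
    mean = x.mean(axis=0)
    if n < d + 1:
        warnings.warn(
            f"n={n} < d+1={d + 1}: covariance is rank-deficient, "
            "falling back to strongly regularized whitening",
            RuntimeWarning,
            stacklevel=2,
        )
    centered = x - mean
    sigma = (centered.T @ centered) / max(n - 1, 1)
    trace = float(np.trace(sigma))
    ridge = 1e-6 * trace / d if trace > 0 else 1e-12
    evals, evecs = np.linalg.eigh(sigma)
    if evals.min() < -1e-8 * max(trace, 1.0):
        raise np.linalg.LinAlgError("covariance is not PSD")
    floor = ridge
    if evals.max() <= 0 or evals.min() < 1e-10 * max(evals.max(), 1.0):
        if n >= d + 1:  # rank-deficiency not already announced above
            warnings.warn(
                "rank-deficient covariance; using regularized whitening",
                RuntimeWarning,
                stacklevel=2,
            )
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 0.0) + floor)) @ evecs.T
    mapped = centered @ inv_sqrt
    radii = np.linalg.norm(mapped, axis=1)
    return OneClassModel(mean=mean, whitener=inv_sqrt, ridge=ridge, radii_fit=radii)


def oc_map(features: FeatureMatrix, model: OneClassModel) -> HypersphereEmbedding:
    """Map features through a fitted one-class model.

    Re-mapping the fitting set reproduces the radii stored at fit time;
    mapping the center point gives radius 0.
    """
    if features.d != model.d:
        raise ValueError(
            f"feature dimension {features.d} does not match model dimension {model.d}"
        )
    mapped = (features.values - model.mean) @ model.whitener
    radii = np.linalg.norm(mapped, axis=1)
    return HypersphereEmbedding(
        mapped=mapped, center=np.zeros(mapped.shape[1]), radii=radii
    )
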