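"""Composite distribution metrics: Frechet distance (FID) and kernel distance (KID).

Both compare the real and synthetic embedding distributions as a whole, so
each score mixes fidelity and diversity.  The Frechet distance treats both
distributions as Gaussians and computes the Wasserstein-2 distance between
the fitted moments; the kernel distance is the unbiased squared maximum
mean discrepancy (MMD^2) under a polynomial kernel, estimated by averaging
over seeded random subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import FeatureMatrix


@dataclass
class GaussianMoments:
    """Sample mean and covariance (divisor n-1) of an embedded distribution."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def d(self) -> int:
        return self.mean.shape[0]


@dataclass
class KernelConfig:
    """Polynomial-kernel MMD estimator settings.

    k(u, v) = (u.v * scale + offset)^degree with the standard cubic kernel
    (degree 3, scale 1/d, offset 1) by default; ``scale=None`` means 1/d.
    The estimator averages the unbiased MMD^2 over ``n_subsets`` random
    subsets of ``subset_size`` samples from each side, drawn without
    replacement with ``seed``.
    """

    degree: int = 3
    scale: float | None = None
    offset: float = 1.0
    subset_size: int = 1000
    n_subsets: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("kernel degree must be >= 1")
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")


def gaussian_moments(features: FeatureMatrix) -> GaussianMoments:
    """Sample mean and covariance (ddof=1) of a feature matrix. Needs n >= 2."""
    x = features.values
    if x.shape[0] < 2:
        raise ValueError("at least 2 samples are required to estimate moments")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return GaussianMoments(mean=mean, covariance=cov, n=x.shape[0])


def _psd_sqrt(matrix: np.ndarray, tol: float) -> np.ndarray:
    evals, evecs = np.linalg.eigh(matrix)
    if evals.min() < -tol:
        raise np.linalg.LinAlgError(
            f"matrix has eigenvalue {evals.min():.3e} below -{tol:.1e}; not PSD"
        )
    return evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T


def frechet_distance(a: GaussianMoments, b: GaussianMoments) -> float:
    """Wasserstein-2 distance between two Gaussians.

        d^2 = ||mu_a - mu_b||^2 + Tr(Sigma_a + Sigma_b - 2 (Sigma_a Sigma_b)^{1/2})

    The cross-term square root is computed via the symmetric eigendecomposition
    of ``sqrt(Sigma_a) Sigma_b sqrt(Sigma_a)`` (numerically stable and exactly
    symmetric in its arguments).  Eigenvalues below -1e-6 (relative to scale)
    raise; tiny negative values from roundoff are clipped to 0, so the result
    is always nonnegative.
    """
    if a.d != b.d:
        raise ValueError(f"dimension mismatch: {a.d} vs {b.d}")
    scale = max(float(np.trace(a.covariance) + np.trace(b.covariance)), 1.0)
    tol = 1e-6 * scale
    sqrt_a = _psd_sqrt(a.covariance, tol)
    inner = sqrt_a @ b.covariance @ sqrt_a
    inner = (inner + inner.T) / 2.0
    evals = np.linalg.eigvalsh(inner)
    if evals.min() < -tol:
        raise np.linalg.LinAlgError(
            f"cross-covariance term has eigenvalue {evals.min():.3e}; "
            "covariances are not PSD within tolerance"
        )
    trace_sqrt = np.sqrt(np.clip(evals, 0.0, None)).sum()
    mean_term = float(np.sum((a.mean - b.mean) ** 2))
    value = mean_term + float(
        np.trace(a.covariance) + np.trace(b.covariance) - 2.0 * trace_sqrt
    )
    return max(value, 0.0)


def _poly_kernel(x: np.ndarray, y: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    scale = cfg.scale if cfg.scale is not None else 1.0 / x.shape[1]
    return (x @ y.T * scale + cfg.offset) ** cfg.degree


def _unbiased_mmd2(x: np.ndarray, y: np.ndarray, cfg: KernelConfig) -> float:
    m, n = x.shape[0], y.shape[0]
    kxx = _poly_kernel(x, x, cfg)
    kyy = _poly_kernel(y, y, cfg)
    kxy = _poly_kernel(x, y, cfg)
    # unbiased estimator: diagonal terms excluded from the within-set sums
    sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    sum_xy = 2.0 * kxy.mean()
    return float(sum_xx + sum_yy - sum_xy)


def kid(
    x: FeatureMatrix, y: FeatureMatrix, cfg: KernelConfig | None = None
) -> tuple[float, float]:
    """Kernel distance between two embedded sets.

    Returns ``(mean, std)`` of the unbiased MMD^2 estimator across
    ``cfg.n_subsets`` seeded random subsets of size ``cfg.subset_size`` from
    each set.  Subset size defaults to ``min(nx, ny, 1000)`` when the
    configured size exceeds the data.
    """
    if cfg is None:
        cfg = KernelConfig(subset_size=min(x.n, y.n, 1000))
    if x.d != y.d:
        raise ValueError(f"dimension mismatch: {x.d} vs {y.d}")
    if cfg.subset_size > min(x.n, y.n):
        raise ValueError(
            f"subset_size={cfg.subset_size} exceeds the smaller set "
            f"(nx={x.n}, ny={y.n})"
        )
    rng = np.random.default_rng(cfg.seed)
    values = np.empty(cfg.n_subsets)
    for i in range(cfg.n_subsets):
        ix = rng.choice(x.n, size=cfg.subset_size, replace=False)
        iy = rng.choice(y.n, size=cfg.subset_size, replace=False)
        values[i] = _unbiased_mmd2(x.values[ix], y.values[iy], cfg)
    return float(values.mean()), float(values.std(ddof=0))
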