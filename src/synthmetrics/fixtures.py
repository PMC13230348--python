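"""Seeded fixture generators emulating generative-model pathologies.

Real data are drawn from a mixture of well-separated spherical Gaussians;
synthetic data are drawn from a perturbed copy of that mixture with three
independently controllable failure modes:

* ``shift`` — a global mean offset of the synthetic cloud (fidelity loss);
* ``mode_drop`` — mixture components absent from the synthetic side
  (diversity collapse / mode dropping);
* ``copy_frac`` + ``jitter_sd`` — a fraction of synthetic samples that are
  jittered copies of real samples (memorization).

A companion image generator produces "phantom" slice stacks — elliptical
pseudo-brains with an intensity gradient and speckle texture — to exercise
the image -> embedding -> metric path end to end without any real MRI data.
All outputs are fully determined by the integer seed via numpy's
``default_rng`` (PCG64), which is stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import FeatureMatrix
from .imaging_io import SliceStack


@dataclass
class ModeSpec:
    """One mixture component: spherical Gaussian N(mean, sd^2 I) with a weight."""

    mean: tuple[float, ...]
    sd: float = 1.0
    weight: float = 1.0


@dataclass
class ScenarioSpec:
    """A real/synthetic feature-cloud scenario.

    Defaults describe a healthy generator at desk scale: two well-separated
    equal-weight modes (separation 6 sd per the well-separated convention,
    here 20 sd), no shift, no dropped modes, no copying.
    """

    n_real: int = 500
    n_synth: int = 500
    d: int = 8
    modes: list[ModeSpec] = field(
        default_factory=lambda: [
            ModeSpec(mean=(0.0,), sd=1.0, weight=0.5),
            ModeSpec(mean=(20.0,), sd=1.0, weight=0.5),
        ]
    )
    shift: float = 0.0
    mode_drop: tuple[int, ...] = ()
    copy_frac: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [m.weight for m in self.modes]
        if not np.isclose(sum(weights), 1.0):
            raise ValueError(f"mode weights must sum to 1, got {sum(weights)}")
        if not 0.0 <= self.copy_frac <= 1.0:
            raise ValueError("copy_frac must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")
        if any(i < 0 or i >= len(self.modes) for i in self.mode_drop):
            raise ValueError("mode_drop indices out of range")
        if len(self.mode_drop) >= len(self.modes):
            raise ValueError("cannot drop every mode: synthetic mixture would be empty")


def _mode_means(spec: ScenarioSpec) -> np.ndarray:
    """Mode means embedded in d dimensions (extra axes zero-filled)."""
    means = np.zeros((len(spec.modes), spec.d))
    for i, mode in enumerate(spec.modes):
        vec = np.asarray(mode.mean, dtype=np.float64)
        if vec.size > spec.d:
            raise ValueError(f"mode {i} mean has more than d={spec.d} coordinates")
        means[i, : vec.size] = vec
    return means


def _sample_mixture(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    assignments = rng.choice(len(weights), size=n, p=weights)
    noise = rng.standard_normal((n, means.shape[1]))
    return means[assignments] + noise * sds[assignments, np.newaxis]


def gen_feature_clouds(spec: ScenarioSpec) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Generate (real, synthetic) feature matrices for a scenario.

    Real samples come from the stated mixture.  Synthetic samples come from
    the mixture with dropped modes removed (surviving weights renormalized)
    and the global shift added; a ``copy_frac`` fraction of them is then
    replaced by jittered copies of randomly chosen real samples
    (copy + N(0, jitter_sd^2) noise).  Everything is drawn from a single
    ``default_rng(seed)`` stream, so the output is reproducible bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    means = _mode_means(spec)
    sds = np.array([m.sd for m in spec.modes])
    weights = np.array([m.weight for m in spec.modes])

    real_values = _sample_mixture(rng, spec.n_real, means, sds, weights)

    keep = np.setdiff1d(np.arange(len(spec.modes)), np.asarray(spec.mode_drop, int))
    synth_weights = weights[keep] / weights[keep].sum()
    synth_values = _sample_mixture(rng, spec.n_synth, means[keep], sds[keep], synth_weights)
    synth_values = synth_values + spec.shift

    n_copies = int(round(spec.copy_frac * spec.n_synth))
    if n_copies > 0:
        targets = rng.choice(spec.n_real, size=n_copies, replace=n_copies > spec.n_real)
        jitter = rng.standard_normal((n_copies, spec.d)) * spec.jitter_sd
        synth_values[:n_copies] = real_values[targets] + jitter

    real = FeatureMatrix(real_values, source="real", extractor_id="scenario")
    synth = FeatureMatrix(synth_values, source="synthetic", extractor_id="scenario")
    return real, synth


def gen_phantom_stack(n: int, size: int = 64, seed: int = 0) -> SliceStack:
    """Generate n phantom slices: centered ellipses with gradient and speckle.

    Each slice is a pseudo-brain on a black background — an ellipse with
    seeded random semi-axes (25-45% of the canvas per axis), a smooth
    left-to-right intensity gradient, and multiplicative speckle texture —
    normalized to [0, 1].  Same seed, same stack, bit for bit.
    """
    if n < 1:
        raise ValueError("need at least one phantom image")
    if size < 8:
        raise ValueError("canvas too small for a phantom")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    images = np.zeros((size, size, n), dtype=np.float32)
    for i in range(n):
        a = rng.uniform(0.25, 0.45) * size
        b = rng.uniform(0.25, 0.45) * size
        angle = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
        v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        gradient = 0.4 + 0.6 * (xx / (size - 1))
        speckle = 1.0 + 0.15 * rng.standard_normal((size, size))
        img = np.where(mask, gradient * speckle, 0.0)
        img = np.clip(img, 0.0, None)
        peak = img.max()
        images[:, :, i] = (img / peak) if peak > 0 else img
    return SliceStack(images, labels=[f"phantom_{i:05d}" for i in range(n)])
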