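"""NIfTI slice-stack I/O and the 2D preprocessing chain.

A *slice stack* is a set of 2D grayscale images (one per subject) stored as
a single 3D NIfTI volume of shape H x W x N, intensities in [0, 1].  The
preprocessing chain turns a registered 3D brain volume into one such slice:
per-volume min-max intensity normalization, central axial slice extraction,
and zero-padding onto a square canvas (the 182x218 MNI-grid slice padded to
256x256 is the motivating case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal
    (e.g. a constant-intensity volume that cannot be rescaled)."""


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    data
        Real-valued array of shape (X, Y, Z); all values finite.
    spacing
        Voxel size per axis in mm. Defaults to isotropic 1 mm (MNI grid).
    orientation
        Free-form orientation tag, e.g. ``"RAS"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


@dataclass
class SliceStack:
    """N grayscale H x W images in [0, 1] stacked along the last axis.

    ``labels`` records per-slice provenance (e.g. subject or sample ids).
    """

    images: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ValueError(f"expected H x W x N array, got ndim={self.images.ndim}")
        if self.images.shape[2] < 1:
            raise ValueError("a slice stack needs at least one slice")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("stack contains non-finite values")
        lo, hi = float(self.images.min()), float(self.images.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1]; observed range [{lo:g}, {hi:g}]"
            )
        if not self.labels:
            self.labels = [f"slice_{i:05d}" for i in range(self.n)]
        if len(self.labels) != self.n:
            raise ValueError("one label per slice required")

    @property
    def n(self) -> int:
        return self.images.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[0], self.images.shape[1]


def normalize_intensity(volume: Volume3D) -> Volume3D:
    """Min-max rescale a volume to [0, 1].

    The rescale is per-volume: ``(x - min) / (max - min)`` over all voxels.
    Idempotent on already-normalized volumes.

    Raises
    ------
    DegenerateInputError
        If the volume is constant (max == min), which admits no rescale.
    """
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi == lo:
        raise DegenerateInputError(
            f"constant volume (all voxels = {lo:g}) cannot be intensity-normalized"
        )
    out = (volume.data - lo) / (hi - lo)
    return Volume3D(out, spacing=volume.spacing, orientation=volume.orientation)


def extract_central_slice(volume: Volume3D, axis: int = 2) -> np.ndarray:
    """Return the central 2D slice along ``axis`` (default axial, axis 2).

    The central index is ``floor(Z / 2)`` with 0-based indexing — for even Z
    the upper of the two middle slices.  A 182x218x182 MNI-registered volume
    yields a 182x218 image at index 91.
    """
    z = volume.data.shape[axis]
    if z < 1:
        raise ValueError("cannot extract a slice from an empty axis")
    return np.take(volume.data, z // 2, axis=axis).copy()


def pad_to_canvas(image: np.ndarray, canvas: int) -> np.ndarray:
    """Zero-pad a 2D image onto a centered ``canvas x canvas`` grid.

    The total pad per axis is split floor (top/left) / ceil (bottom/right),
    so a 182x218 slice on a 256 canvas gets a 37-pixel top and 19-pixel left
    margin. Padding never crops: an image larger than the canvas is an error.
    The sum of pixel intensities is preserved exactly.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    h, w = image.shape
    if h > canvas or w > canvas:
        raise ValueError(
            f"image {h}x{w} exceeds canvas {canvas}x{canvas}; cropping is not supported"
        )
    top = (canvas - h) // 2
    left = (canvas - w) // 2
    out = np.zeros((canvas, canvas), dtype=image.dtype)
    out[top : top + h, left : left + w] = image
    return out


def stack_slices(images: list[np.ndarray], labels: list[str] | None = None) -> SliceStack:
    """Stack same-shaped 2D images (each in [0, 1]) into a SliceStack.

    Order is preserved: slice i of the stack is ``images[i]``.
    """
    if len(images) == 0:
        raise ValueError("cannot stack zero images")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"mixed image shapes: {sorted(shapes)}")
    data = np.stack([np.asarray(im, dtype=np.float32) for im in images], axis=2)
    return SliceStack(data, labels=labels or [])


def write_stack(stack: SliceStack, path) -> None:
    """Write a SliceStack as a single-file NIfTI-1 volume.

    Slices run along the third axis; the affine is identity-scaled; pixel
    data is stored as 32-bit float so the round-trip is bit-exact.
    """
    img = nib.Nifti1Image(stack.images.astype(np.float32), affine=np.eye(4))
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def read_stack(path, normalize: bool = False) -> SliceStack:
    """Read a NIfTI file as a SliceStack (last axis = slice index).

    A 2D file becomes a stack with N = 1.  Intensities outside [0, 1] are
    rejected unless ``normalize=True``, in which case a per-file min-max
    rescale is applied first.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D or 3D NIfTI file, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"file {path!r} contains non-finite values")
    lo, hi = float(data.min()), float(data.max())
    if lo < 0.0 or hi > 1.0:
        if not normalize:
            raise ValueError(
                f"intensities in {path!r} span [{lo:g}, {hi:g}], outside [0, 1]; "
                "pass normalize=True to rescale"
            )
        if hi == lo:
            raise DegenerateInputError("constant file cannot be normalized")
        data = (data - lo) / (hi - lo)
    return SliceStack(data)


def export_slice_png(stack: SliceStack, index: int, path) -> None:
    """Export one slice as an 8-bit grayscale PNG (for human review sessions)."""
    from PIL import Image

    if not 0 <= index < stack.n:
        raise IndexError(f"slice index {index} out of range for N={stack.n}")
    arr = (stack.images[:, :, index] * 255.0).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))
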