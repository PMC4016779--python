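"""Noise suppression and binary segmentation.

The processing chain mirrors scanner-software practice for HR-pQCT
trabecular analysis: a small truncated Gaussian kernel (sigma 0.7 voxels,
support 1 voxel, i.e. a renormalized 3x3x3 stencil) followed by a fixed
fractional threshold (11% of the maximal gray value) applied uniformly to
all specimens.

"Support" is read as the truncation radius of the kernel in voxels: the
kernel covers a ``(2*support+1)**3`` neighborhood, is sampled at integer
offsets and renormalized to sum 1, so constant volumes pass unchanged.
The threshold reference is configurable: the per-image maximum (after
filtering), or a fixed full-scale ceiling such as the scanner's native
gray-value range.  The comparison is ``>=`` so the boundary value is
foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume3D


@dataclass
class FilterParams:
    """Truncated Gaussian kernel: ``sigma`` and truncation radius ``support``
    both in voxels."""

    sigma: float = 0.7
    support: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.support < 0 or int(self.support) != self.support:
            raise ValueError("support must be a non-negative integer")
        self.support = int(self.support)


@dataclass
class ThresholdParams:
    """Fixed fractional threshold for binary segmentation.

    ``reference='image_max'`` uses the per-image maximum; ``'full_scale'``
    uses ``full_scale_value`` (e.g. a fixed 16-bit ceiling).
    """

    fraction: float = 0.11
    reference: str = "image_max"
    full_scale_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie strictly between 0 and 1")
        if self.reference not in ("image_max", "full_scale"):
            raise ValueError(f"unknown threshold reference '{self.reference}'")
        if self.reference == "full_scale" and self.full_scale_value is None:
            raise ValueError("full_scale reference requires full_scale_value")


def gaussian_kernel(params: FilterParams) -> np.ndarray:
    """The sampled, truncated, renormalized 3D Gaussian kernel."""
    s = params.support
    ax = np.arange(-s, s + 1, dtype=float)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    if params.sigma == 0:
        k = ((dx == 0) & (dy == 0) & (dz == 0)).astype(float)
    else:
        k = np.exp(-(dx**2 + dy**2 + dz**2) / (2.0 * params.sigma**2))
    return k / k.sum()


def gaussian_filter(vol: Volume3D, params: FilterParams | None = None) -> Volume3D:
    """Smooth a gray-level volume with the truncated Gaussian kernel.

    Borders are handled by mirror reflection; ``sigma == 0`` or
    ``support == 0`` return the input unchanged (as a copy).
    """
    if params is None:
        params = FilterParams()
    if params.sigma == 0 or params.support == 0:
        return vol.like(vol.data.astype(float, copy=True))
    kernel = gaussian_kernel(params)
    out = ndimage.correlate(vol.data.astype(float), kernel, mode="mirror")
    return vol.like(out)


def binarize(vol: Volume3D, params: ThresholdParams | None = None) -> Volume3D:
    """Segment bone with threshold ``fraction x reference``; ties -> foreground."""
    if params is None:
        params = ThresholdParams()
    if params.reference == "image_max":
        ref = float(np.max(vol.data))
        if ref <= 0:
            raise ValueError(
                "image_max threshold reference requires a positive maximum")
    else:
        ref = float(params.full_scale_value)
    t = params.fraction * ref
    return vol.like((vol.data >= t).astype(np.uint8))
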