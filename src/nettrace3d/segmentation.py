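"""Binarization and binary clean-up.

Thresholding (Otsu by default, or a percentage of the maximum intensity)
turns the gray-scale stack into a boolean mask; morphological closing fills
small holes and compacts surfaces; island removal drops small disconnected
components.  Connectivity is 26-neighborhood throughout, matching the
skeleton-graph adjacency downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import ImageStack

__all__ = [
    "BinaryStack",
    "compute_threshold",
    "binarize",
    "morphological_close",
    "remove_islands",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryStack:
    """Boolean 3D mask (z, y, x) with voxel size bookkeeping."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel dimensions must be positive")
        self.voxel_size = vs

    @property
    def is_isotropic(self) -> bool:
        vx, vy, vz = self.voxel_size
        ref = max(vx, vy, vz)
        return abs(vx - vy) <= 1e-6 * ref and abs(vy - vz) <= 1e-6 * ref

    @property
    def edge(self) -> float:
        """Isotropic voxel edge in μm; raises for anisotropic masks."""
        if not self.is_isotropic:
            raise ValueError("voxel size is anisotropic; resample first")
        return self.voxel_size[0]

    @property
    def voxel_volume(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz


def compute_threshold(stack: ImageStack, method: str = "otsu",
                      value: float | None = None) -> float:
    """Threshold intensity for binarization.

    otsu: the gray level maximizing the between-class variance of the
    foreground/background split, over a 256-bin histogram spanning the
    observed intensity range; ties break toward the lower level.
    percentage: ``value`` percent of the maximum intensity.
    """
    data = np.asarray(stack.data)
    if method == "percentage":
        if value is None or not (0 < value <= 100):
            raise ValueError("percentage method needs a value in (0, 100]")
        return float(data.max()) * value / 100.0
    if method != "otsu":
        raise ValueError(f"unsupported method {method!r}")

    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("degenerate histogram: constant image under otsu")
    counts, edges = np.histogram(data, bins=256, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(counts)                      # voxels in bins <= k
    m0 = np.cumsum(counts * centers)
    w1 = total - w0
    mean_total = m0[-1]
    # between-class variance for split after bin k (k = 0..254)
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    var_between = np.zeros(255)
    mu0 = np.where(w0[:-1] > 0, m0[:-1] / np.maximum(w0[:-1], 1), 0.0)
    mu1 = np.where(w1[:-1] > 0,
                   (mean_total - m0[:-1]) / np.maximum(w1[:-1], 1), 0.0)
    var_between[valid] = (w0[:-1][valid] * w1[:-1][valid]
                          * (mu0[valid] - mu1[valid]) ** 2)
    k = int(np.argmax(var_between))             # argmax takes the lowest tie
    # mask = intensity >= threshold must put bins > k in the foreground
    return float(edges[k + 1])


def binarize(stack: ImageStack, threshold: float) -> BinaryStack:
    """Mask of voxels with intensity >= threshold (>= by convention)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryStack(np.asarray(stack.data) >= threshold, stack.voxel_size,
                       threshold_used=float(threshold))


def morphological_close(binary: BinaryStack, iterations: int = 5
                        ) -> BinaryStack:
    """``iterations`` dilations then equally many erosions (3³, 26-connected).

    Fills holes and gaps up to roughly 2·iterations voxels across; 0
    iterations is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryStack(binary.mask.copy(), binary.voxel_size,
                           binary.threshold_used)
    mask = ndimage.binary_dilation(binary.mask, _STRUCT26,
                                   iterations=iterations)
    mask = ndimage.binary_erosion(mask, _STRUCT26, iterations=iterations)
    mask |= binary.mask      # closing never removes original foreground
    return BinaryStack(mask, binary.voxel_size, binary.threshold_used)


def remove_islands(binary: BinaryStack, min_volume_um3: float = 100.0
                   ) -> BinaryStack:
    """Drop 26-connected components with physical volume < min_volume_um3.

    Components at or above the threshold are kept untouched (strict <).
    """
    if min_volume_um3 < 0:
        raise ValueError("minimum island volume must be >= 0")
    if min_volume_um3 == 0:
        return BinaryStack(binary.mask.copy(), binary.voxel_size,
                           binary.threshold_used)
    labels, n = ndimage.label(binary.mask, structure=_STRUCT26)
    if n == 0:
        return BinaryStack(binary.mask.copy(), binary.voxel_size,
                           binary.threshold_used)
    sizes = np.bincount(labels.ravel())
    keep = sizes * binary.voxel_volume >= min_volume_um3
    keep[0] = False
    return BinaryStack(keep[labels], binary.voxel_size,
                       binary.threshold_used)
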