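"""Optional image conditioning ahead of segmentation.

Four steps, each usable on its own: a despeckling median filter, a
depth-attenuation (z-drop) correction for the exponential signal loss of
optical slice microscopy, resampling to an isotropic voxel size, and a 3D
Gaussian blur.  The reference order is median → z-drop → resample → Gaussian.
All steps work in float32 and preserve the voxel-size bookkeeping.

The attenuation model is I_A(z) = a·exp(b·z): the mean intensity of the slice
at physical depth z μm, with a the reference intensity at z = 0 and b the
decay rate per μm (negative for absorption).  The correction divides each
slice by exp(b·z), restoring a flat mean-intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .io_formats import ImageStack

__all__ = [
    "AttenuationFit",
    "median_filter",
    "fit_attenuation",
    "correct_attenuation",
    "resample_isotropic",
    "gaussian_smooth",
]


@dataclass
class AttenuationFit:
    """Exponential fit a·exp(b·z) to per-slice mean intensities."""

    a: float                       # reference intensity at z = 0
    b: float                       # decay rate per μm
    slice_means: list[tuple[float, float]]   # (z position μm, mean intensity)
    residual: float                # sum of squared residuals
    fallback: bool = False         # True if only the log-linear estimate held


def median_filter(stack: ImageStack, size: int = 3) -> ImageStack:
    """Replace each voxel by the median of its size³ neighborhood.

    Borders are edge-replicated.  size must be odd; the default 3 removes
    single-voxel speckles and extrema.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("median filter size must be odd and >= 1")
    data = ndimage.median_filter(
        np.asarray(stack.data, dtype=np.float32), size=size, mode="nearest")
    return ImageStack(data, stack.voxel_size, stack.channel, stack.source)


def _slice_positions(stack: ImageStack) -> np.ndarray:
    return np.arange(stack.data.shape[0], dtype=float) * stack.voxel_size[2]


def fit_attenuation(stack: ImageStack) -> AttenuationFit:
    """Fit a·exp(b·z) to the mean intensity of each slice.

    Non-linear least squares, initialised from a log-linear regression on the
    positive slice means; if the optimizer fails to produce a finite result
    the log-linear estimate is returned with ``fallback=True``.
    """
    if stack.data.shape[0] < 3:
        raise ValueError("attenuation fit needs at least 3 slices")
    z = _slice_positions(stack)
    means = np.asarray(stack.data, dtype=np.float64).mean(axis=(1, 2))
    if not np.any(means > 0):
        raise ValueError("attenuation fit needs a nonzero slice mean")

    positive = means > 0
    slope, intercept = np.polyfit(z[positive], np.log(means[positive]), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)

    fallback = False
    try:
        (a, b), _ = optimize.curve_fit(
            lambda zz, a, b: a * np.exp(b * zz), z, means, p0=(a0, b0),
            maxfev=10000)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0):
            raise RuntimeError("non-finite fit")
    except (RuntimeError, optimize.OptimizeWarning):
        a, b, fallback = a0, b0, True
    residual = float(np.sum((means - a * np.exp(b * z)) ** 2))
    return AttenuationFit(float(a), float(b),
                          list(zip(z.tolist(), means.tolist())), residual,
                          fallback)


def correct_attenuation(stack: ImageStack, fit: AttenuationFit) -> ImageStack:
    """Undo the fitted depth attenuation: slice at depth z × exp(−b·z).

    Normalises to the z = 0 level, so corrected slice means sit at the fitted
    reference intensity a.
    """
    z = _slice_positions(stack)
    gain = np.exp(-fit.b * z).astype(np.float32)
    data = np.asarray(stack.data, dtype=np.float32) * gain[:, None, None]
    return ImageStack(data, stack.voxel_size, stack.channel, stack.source)


def resample_isotropic(stack: ImageStack,
                       target_edge: float | None = None) -> ImageStack:
    """Resample to a cubic voxel of edge ``target_edge`` μm.

    Defaults to the smallest of the three voxel dimensions (so detail is
    never discarded).  Third-order spline interpolation; axis lengths scale
    by old_edge/target and round to the nearest integer.
    """
    vx, vy, vz = stack.voxel_size
    edge = float(target_edge) if target_edge else min(vx, vy, vz)
    if edge <= 0:
        raise ValueError("target edge must be positive")
    extent = (stack.data.shape[2] * vx, stack.data.shape[1] * vy,
              stack.data.shape[0] * vz)
    if edge > min(extent):
        raise ValueError("target edge exceeds the stack extent")
    zoom = (vz / edge, vy / edge, vx / edge)
    if all(abs(f - 1.0) < 1e-9 for f in zoom):
        return ImageStack(np.asarray(stack.data, dtype=np.float32),
                          (edge, edge, edge), stack.channel, stack.source)
    data = ndimage.zoom(np.asarray(stack.data, dtype=np.float32), zoom,
                        order=3, mode="nearest", grid_mode=False)
    return ImageStack(np.clip(data, 0, None), (edge, edge, edge),
                      stack.channel, stack.source)


def gaussian_smooth(stack: ImageStack, sigma: float = 2.0) -> ImageStack:
    """3D Gaussian blur with reflective borders; sigma in voxels."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return ImageStack(np.asarray(stack.data, dtype=np.float32),
                          stack.voxel_size, stack.channel, stack.source)
    data = ndimage.gaussian_filter(
        np.asarray(stack.data, dtype=np.float32), sigma=sigma, mode="reflect")
    return ImageStack(data, stack.voxel_size, stack.channel, stack.source)
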