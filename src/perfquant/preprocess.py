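"""Optional preprocessing before deconvolution.

Three independent, individually optional steps:

* weighted-mean denoising (2D in-slice, 3D spatial, or 4D spatial+time),
  exploiting the spatial continuity of perfusion — blood flows between
  neighbouring voxels, so true intensity varies smoothly;
* baseline correction — subtracting the pre-bolus plateau turns a raw
  intensity curve into a concentration-like signal that starts near zero;
* brain masking by thresholding time-averaged intensity, so air/background
  voxels are never deconvolved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DimensionError
from .series_io import Layout, PerfusionSeries

__all__ = [
    "KernelSpec",
    "denoise_weighted_mean",
    "baseline_correct",
    "compute_brain_mask",
]

# voxel_major axes are (z, y, x, t); which of them each kernel ndim covers
_KERNEL_AXES = {2: (1, 2), 3: (0, 1, 2), 4: (0, 1, 2, 3)}


@dataclass
class KernelSpec:
    """A weighted-mean filter window.

    ``ndim`` selects the neighbourhood: 2 = in-slice (y, x), 3 = spatial
    (z, y, x), 4 = spatial + time.  ``radius`` is the half-width per included
    axis, so the window spans ``2*radius + 1`` samples along each.  ``weights``
    is either the string ``"uniform"`` or an explicit nonnegative array of
    shape ``(2*radius+1,) * ndim``; weights are normalised at application time.
    """

    ndim: int = 3
    radius: int = 1
    weights: np.ndarray | str = "uniform"

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3, 4):
            raise ConfigurationError(f"kernel ndim must be 2, 3 or 4, got {self.ndim}")
        if self.radius < 0:
            raise ConfigurationError(f"kernel radius must be >= 0, got {self.radius}")

    def resolve(self) -> np.ndarray:
        """Return the explicit weight array, validated."""
        side = 2 * self.radius + 1
        shape = (side,) * self.ndim
        if isinstance(self.weights, str):
            if self.weights != "uniform":
                raise ConfigurationError(f"unknown kernel weights {self.weights!r}")
            w = np.ones(shape, dtype=np.float64)
        else:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != shape:
                raise DimensionError(
                    f"kernel weights shape {w.shape} != expected {shape} "
                    f"for ndim={self.ndim}, radius={self.radius}"
                )
            if np.any(w < 0):
                raise ConfigurationError("kernel weights must be nonnegative")
        if not w.sum() > 0:
            raise ConfigurationError("kernel weights must have positive total weight")
        return w


def denoise_weighted_mean(series: PerfusionSeries, kernel: KernelSpec) -> PerfusionSeries:
    """Weighted-mean filter over each voxel's neighbourhood.

    Border policy is truncate-and-renormalise: the window is clipped at the
    volume edge and the weights of in-bounds neighbours are renormalised, so
    edges are neither darkened (as zero padding would) nor duplicated.
    Implemented as the ratio of two correlations — data*w over coverage*w —
    which is exactly that truncated weighted mean.
    """
    if series.layout is not Layout.VOXEL_MAJOR:
        raise DimensionError("denoise_weighted_mean expects a voxel_major series")
    w = kernel.resolve()
    shape4 = [1, 1, 1, 1]
    for ax, n in zip(_KERNEL_AXES[kernel.ndim], w.shape):
        shape4[ax] = n
    w4 = w.reshape(shape4)
    data = np.asarray(series.data, dtype=np.float64)
    num = ndimage.correlate(data, w4, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(data), w4, mode="constant", cval=0.0)
    return replace(series, data=num / den)


def baseline_correct(series: PerfusionSeries, n_baseline: int) -> PerfusionSeries:
    """Subtract each voxel's mean over the first ``n_baseline`` frames.

    Valid range is ``1 <= n_baseline < Time``.  The result may be negative —
    downstream map computation treats sub-baseline excursions as noise.
    """
    nt = series.n_time
    if not 1 <= n_baseline < nt:
        raise ConfigurationError(
            f"n_baseline must be in [1, {nt - 1}], got {n_baseline}"
        )
    t_axis = 0 if series.layout is Layout.TIME_MAJOR else 3
    idx = [slice(None)] * 4
    idx[t_axis] = slice(0, n_baseline)
    base = series.data[tuple(idx)].mean(axis=t_axis, keepdims=True)
    return replace(series, data=series.data - base)


def compute_brain_mask(series: PerfusionSeries, frac: float) -> np.ndarray:
    """Boolean (z, y, x) mask of voxels with appreciable mean intensity.

    A voxel is inside the mask iff its time-averaged intensity is at least
    ``frac`` times the maximum time-averaged intensity anywhere in the volume.
    Intended to run on raw (pre-baseline-correction) intensities.
    """
    if not 0 < frac < 1:
        raise ConfigurationError(f"mask fraction must be in (0, 1), got {frac}")
    t_axis = 0 if series.layout is Layout.TIME_MAJOR else 3
    mean_img = series.data.mean(axis=t_axis)  # (z, y, x) either way
    peak = mean_img.max()
    if peak <= 0:  # no signal anywhere: empty mask, not an all-true one
        return np.zeros(mean_img.shape, dtype=bool)
    return mean_img >= frac * peak
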