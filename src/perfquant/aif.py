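"""Arterial input functions and their convolution matrices.

The arterial input function (AIF) Ca(t) is the contrast concentration in a
feeding artery; tissue curves are modelled as its convolution with the tissue
impulse response.  Discretised on the acquisition grid the convolution operator
is the dt-scaled lower-triangular Toeplitz matrix

    Ca_mat[i, j] = dt * Ca(t_{i-j+1})   for i >= j (1-based),  0 above.

A *global* AIF is one curve for the whole brain, picked from voxels that look
arterial (high, early bolus).  A *local* AIF is selected per voxel from a small
neighbourhood, which tolerates regionally delayed contrast arrival (the global
assumption fails in acute stroke).  Selection here scores each candidate curve
by peak height / (1 + time-to-peak index) — vessels have tall, early peaks —
and averages the top-k; the score is a documented, replaceable default, and an
externally measured AIF (vector file or label volume) bypasses selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .errors import ConfigurationError, DimensionError
from .series_io import Layout, PerfusionSeries

__all__ = [
    "AIFVector",
    "AIFMatrix",
    "build_aif_matrix",
    "select_global_aif",
    "generate_local_aif",
    "read_aif_text",
    "aif_from_labels",
]


@dataclass
class AIFVector:
    """An arterial concentration curve Ca(t_1)..Ca(t_N) on a dt grid."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise DimensionError("AIF must be a non-empty 1D sequence")
        if not self.dt > 0:
            raise ConfigurationError(f"AIF dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class AIFMatrix:
    """The dt-scaled lower-triangular Toeplitz convolution operator of an AIF."""

    matrix: np.ndarray
    dt: float
    source: AIFVector


def build_aif_matrix(aif: AIFVector) -> AIFMatrix:
    """Build the discrete convolution matrix of an AIF.

    Row i, column j (0-based) holds ``dt * Ca[i - j]`` for ``i >= j`` and 0
    above the diagonal; the matrix is constant along every diagonal.  It is
    invertible iff ``Ca[0] != 0`` (triangular determinant ``(dt*Ca[0])**N``).
    """
    first_col = aif.dt * aif.values
    first_row = np.zeros_like(first_col)
    first_row[0] = first_col[0]
    return AIFMatrix(matrix=toeplitz(first_col, first_row), dt=aif.dt, source=aif)


def _score_curves(curves: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arterial-likeness score per curve: peak / (1 + time-to-peak index)."""
    peaks = curves.max(axis=1)
    ttp_idx = curves.argmax(axis=1)
    return peaks / (1.0 + ttp_idx), peaks


def _top_k_mean(curves: np.ndarray, flat_idx: np.ndarray, top_k: int) -> np.ndarray:
    """Mean of the top_k curves by (score desc, flat voxel index asc).

    Averaged about the best-scoring curve (pivot + mean of deviations): this
    limits cancellation, and when the selected curves are identical the result
    is bitwise equal to any of them.
    """
    scores, _ = _score_curves(curves)
    # lexsort: last key is primary; negate score for descending order
    order = np.lexsort((flat_idx, -scores))
    sel = curves[order[:top_k]]
    pivot = sel[0]
    return pivot + (sel - pivot).mean(axis=0)


def _masked_curves(series: PerfusionSeries, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if series.layout is not Layout.VOXEL_MAJOR:
        raise DimensionError("AIF selection expects a voxel_major series")
    if mask.shape != series.spatial_shape:
        raise DimensionError(
            f"mask shape {mask.shape} != spatial shape {series.spatial_shape}"
        )
    flat_idx = np.flatnonzero(mask.ravel())
    curves = series.data.reshape(-1, series.n_time)[flat_idx]
    return curves, flat_idx


def select_global_aif(series: PerfusionSeries, mask: np.ndarray, top_k: int = 5) -> AIFVector:
    """One AIF for the whole volume: mean of the top_k most arterial curves.

    Every in-mask voxel curve is scored by peak/(1+TTP index); ties are broken
    by ascending flat (z-major) voxel index so the choice is deterministic.
    """
    if top_k < 1:
        raise ConfigurationError(f"top_k must be >= 1, got {top_k}")
    curves, flat_idx = _masked_curves(series, mask)
    if curves.shape[0] < top_k:
        raise ConfigurationError(
            f"mask has {curves.shape[0]} voxels, fewer than top_k={top_k}"
        )
    return AIFVector(_top_k_mean(curves, flat_idx, top_k), series.dt)


def generate_local_aif(
    series: PerfusionSeries,
    voxel: tuple[int, int, int],
    radius: int,
    top_k: int,
    fallback: AIFVector,
    mask: np.ndarray | None = None,
) -> AIFVector:
    """AIF for one voxel from its cubic neighbourhood of side ``2*radius+1``.

    Applies the global scoring restricted to in-mask voxels within the cube
    (clipped at the volume edge).  If fewer than ``top_k`` candidates have a
    strictly positive peak the neighbourhood contains no usable vessel signal
    and ``fallback`` (normally the global AIF) is returned instead.
    """
    x, y, z = voxel
    nz, ny, nx = series.spatial_shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise DimensionError(f"voxel {voxel} outside volume {(nx, ny, nz)}")
    if radius < 1:
        raise ConfigurationError(f"local AIF radius must be >= 1, got {radius}")
    sub = np.zeros(series.spatial_shape, dtype=bool)
    sub[
        max(z - radius, 0) : z + radius + 1,
        max(y - radius, 0) : y + radius + 1,
        max(x - radius, 0) : x + radius + 1,
    ] = True
    if mask is not None:
        sub &= mask
    curves, flat_idx = _masked_curves(series, sub)
    if curves.shape[0] == 0:
        return fallback
    positive = curves.max(axis=1) > 0
    if positive.sum() < top_k:
        return fallback
    curves, flat_idx = curves[positive], flat_idx[positive]
    return AIFVector(_top_k_mean(curves, flat_idx, top_k), series.dt)


def read_aif_text(path, dt: float) -> AIFVector:
    """Read an AIF from a plain-text file, one value per line."""
    values = np.loadtxt(str(path), dtype=np.float64, ndmin=1)
    return AIFVector(values, dt)


def aif_from_labels(series: PerfusionSeries, labels: np.ndarray, label: int = 1) -> AIFVector:
    """Average the curves of voxels carrying ``label`` in a label volume."""
    if series.layout is not Layout.VOXEL_MAJOR:
        raise DimensionError("aif_from_labels expects a voxel_major series")
    sel = labels == label
    if sel.shape != series.spatial_shape:
        raise DimensionError(
            f"label volume shape {sel.shape} != spatial shape {series.spatial_shape}"
        )
    if not sel.any():
        raise ConfigurationError(f"label volume contains no voxel with label {label}")
    return AIFVector(series.data[sel].mean(axis=0), series.dt)
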