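"""Truncated-SVD deconvolution.

The tissue curve is Ct = Ca_mat · h + noise, with Ca_mat the lower-triangular
Toeplitz AIF matrix.  Its rows are near-linear combinations of each other, so
direct inversion amplifies noise enormously: the problem is ill-posed, and the
conditioning worsens as the number of time points grows.  Truncated SVD
regularises it — factor Ca_mat = U·diag(w)·Vᵀ, zero every singular value below
a threshold, and pseudoinvert the rest:

    Ca⁺ = V · diag(1/w_i or 0) · Uᵀ,      h = Ca⁺ · Ct.

The threshold is *relative*: w_i is dropped when w_i < rel_threshold · w_max,
which is invariant under rescaling of the AIF.  Boundary values (exactly equal
to the threshold) are kept.  The default, 0.2·w_max, is the value commonly used
for perfusion deconvolution; at threshold 0 the pseudoinverse of an invertible
matrix is its exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aif import AIFMatrix
from .errors import ConfigurationError, DimensionError

__all__ = [
    "TruncatedSVDResult",
    "IRF",
    "truncated_svd",
    "truncated_pseudoinverse",
    "deconvolve_voxel",
]

DEFAULT_REL_THRESHOLD = 0.2


@dataclass
class TruncatedSVDResult:
    """SVD factors of an AIF matrix plus the truncation bookkeeping.

    ``U @ np.diag(W) @ V.T`` reconstructs the input (truncation only affects
    the pseudoinverse); ``W`` is descending; ``retained_rank`` counts singular
    values that survive ``w_i >= rel_threshold * W[0]``.
    """

    U: np.ndarray
    W: np.ndarray
    V: np.ndarray
    rel_threshold: float
    retained_rank: int


@dataclass
class IRF:
    """A deconvolved impulse-response (residue) curve h(t_1)..h(t_N)."""

    values: np.ndarray
    dt: float


def _as_matrix(ca: AIFMatrix | np.ndarray) -> np.ndarray:
    return ca.matrix if isinstance(ca, AIFMatrix) else np.asarray(ca, dtype=np.float64)


def truncated_svd(ca: AIFMatrix | np.ndarray, rel_threshold: float) -> TruncatedSVDResult:
    """Factor the AIF matrix and record which singular values survive."""
    if not 0 <= rel_threshold < 1:
        raise ConfigurationError(
            f"relative SVD threshold must be in [0, 1), got {rel_threshold}"
        )
    a = _as_matrix(ca)
    u, w, vt = np.linalg.svd(a)
    keep = ~(w < rel_threshold * w[0])  # strict less-than is truncated
    retained = int(np.count_nonzero(keep & (w > 0)))
    if retained == 0:
        raise ConfigurationError("all singular values truncated (zero matrix?)")
    return TruncatedSVDResult(
        U=u, W=w, V=vt.T, rel_threshold=rel_threshold, retained_rank=retained
    )


def truncated_pseudoinverse(ca: AIFMatrix | np.ndarray, rel_threshold: float) -> np.ndarray:
    """Regularised pseudoinverse V·diag(1/w or 0)·Uᵀ of the AIF matrix."""
    res = truncated_svd(ca, rel_threshold)
    w = res.W
    inv_w = np.zeros_like(w)
    keep = ~(w < rel_threshold * w[0]) & (w > 0)
    inv_w[keep] = 1.0 / w[keep]
    return (res.V * inv_w) @ res.U.T


def deconvolve_voxel(ct: np.ndarray, ca_pinv: np.ndarray, dt: float) -> IRF:
    """Recover one voxel's impulse response: h = Ca⁺ · Ct."""
    ct = np.asarray(ct, dtype=np.float64)
    if ct.ndim != 1 or ca_pinv.shape != (ct.size, ct.size):
        raise DimensionError(
            f"curve length {ct.shape} incompatible with pseudoinverse {ca_pinv.shape}"
        )
    return IRF(values=ca_pinv @ ct, dt=dt)
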