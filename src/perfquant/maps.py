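"""Hemodynamic parameter maps from impulse responses and tissue curves.

Per voxel, from the deconvolved impulse response h(t):

* CBF — the maximum of h over time (IRF-amplitude units);
* CBV — the rectangle-rule time integral ``dt * sum(max(h, 0))``
  (amplitude·seconds); negative lobes, which are truncation artifacts, are
  clipped in the sum only, so CBV stays nonnegative without touching the peak;
* MTT — CBV / CBF (seconds), by the central volume theorem.

A voxel is *invalid* (NaN in every map) when CBF <= 0 or CBV <= 0.  From the
concentration curve itself:

* TTP — time of the curve's maximum (first occurrence on ties);
* TA  — bolus arrival, the first time the curve reaches ``rise_frac`` of its
  maximum; both NaN when the curve never rises above zero.

Maps can be rendered to per-slice RGB images through a fixed 256-entry
blue-to-red lookup table after percentile windowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decon import IRF
from .errors import ConfigurationError

__all__ = [
    "ParametricMaps",
    "compute_scalar_maps",
    "compute_timing_maps",
    "blue_red_lut",
    "render_colormap",
]

DEFAULT_RISE_FRAC = 0.1


@dataclass
class ParametricMaps:
    """The five 3D parametric volumes plus their shared validity mask.

    All arrays are ``(Dim3, Dim2, Dim1)`` = (z, y, x).  Where ``valid`` is
    False every map holds NaN.  Units: cbf in IRF-amplitude units, cbv in
    amplitude·seconds, mtt/ttp/ta in seconds.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    ta: np.ndarray
    valid: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cbf": self.cbf, "cbv": self.cbv, "mtt": self.mtt,
                "ttp": self.ttp, "ta": self.ta}


def compute_scalar_maps(h: IRF | np.ndarray, dt: float | None = None):
    """(cbf, cbv, mtt) from one impulse response, or None if degenerate.

    ``dt`` is taken from the IRF when one is passed.  Returns None when the
    response has no positive peak or no positive area — such voxels carry no
    interpretable perfusion signal and are marked invalid.
    """
    if isinstance(h, IRF):
        dt = h.dt
        h = h.values
    if dt is None:
        raise ConfigurationError("dt required when h is a bare array")
    h = np.asarray(h, dtype=np.float64)
    cbf = float(h.max())
    cbv = float(dt * np.maximum(h, 0.0).sum())
    if cbf <= 0.0 or cbv <= 0.0:
        return None
    return cbf, cbv, cbv / cbf


def compute_timing_maps(ct: np.ndarray, dt: float, rise_frac: float = DEFAULT_RISE_FRAC):
    """(ttp, ta) in seconds from one concentration curve.

    ttp = dt * argmax (first maximum on ties); ta = dt * first index where the
    curve reaches ``rise_frac`` of its maximum.  Both NaN for curves that never
    go positive.
    """
    if not 0 < rise_frac < 1:
        raise ConfigurationError(f"rise_frac must be in (0, 1), got {rise_frac}")
    ct = np.asarray(ct, dtype=np.float64)
    if ct.size < 2:
        raise ConfigurationError("need at least 2 time points for timing maps")
    peak = ct.max()
    if peak <= 0.0:
        return (np.nan, np.nan)
    ttp = dt * int(ct.argmax())
    ta = dt * int(np.argmax(ct >= rise_frac * peak))
    return (ttp, ta)


def blue_red_lut() -> np.ndarray:
    """Fixed 256x3 uint8 lookup table, blue -> cyan -> green -> yellow -> red."""
    stops = np.array([0, 64, 128, 191, 255], dtype=np.float64)
    r = np.array([0, 0, 0, 255, 255], dtype=np.float64)
    g = np.array([0, 255, 255, 255, 0], dtype=np.float64)
    b = np.array([255, 255, 0, 0, 0], dtype=np.float64)
    idx = np.arange(256, dtype=np.float64)
    lut = np.stack(
        [np.interp(idx, stops, r), np.interp(idx, stops, g), np.interp(idx, stops, b)],
        axis=1,
    )
    return np.rint(lut).astype(np.uint8)


def render_colormap(
    map3d: np.ndarray,
    valid: np.ndarray,
    lo_pct: float = 2.0,
    hi_pct: float = 98.0,
    lut: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Render a parametric volume as one RGB image per axial slice.

    Valid voxels are windowed to the [lo_pct, hi_pct] percentile range of the
    valid values, linearly mapped to LUT indices 0..255 (a degenerate window
    maps everything to index 0), and coloured through the fixed blue-to-red
    table; invalid voxels are black.  Returns a list of (Dim2, Dim1, 3) uint8
    arrays, one per z slice.
    """
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ConfigurationError(f"bad percentile window [{lo_pct}, {hi_pct}]")
    if lut is None:
        lut = blue_red_lut()
    map3d = np.asarray(map3d, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    rgb = np.zeros(map3d.shape + (3,), dtype=np.uint8)
    vals = map3d[valid]
    if vals.size:
        lo, hi = np.percentile(vals, [lo_pct, hi_pct])
        if hi > lo:
            finite = np.where(valid, map3d, lo)  # NaNs sit on invalid voxels
            scaled = (np.clip(finite, lo, hi) - lo) * (255.0 / (hi - lo))
            idx = np.rint(scaled).astype(np.intp)
        else:
            idx = np.zeros(map3d.shape, dtype=np.intp)
        rgb[valid] = lut[idx[valid]]
    return [rgb[z] for z in range(rgb.shape[0])]
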