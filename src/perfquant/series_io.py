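"""Reading, writing and reshaping 4D perfusion series.

A perfusion acquisition is a time series of 3D brain volumes.  Scanners (and
NIfTI files) store it frame by frame — all voxels of one time point together —
which is the wrong memory order for voxel-wise deconvolution, where each voxel's
whole time-concentration curve is needed at once.  This module owns the
:class:`PerfusionSeries` container, the transform between the two layouts, and
NIfTI-1 input/output.

Axis conventions
----------------
``Dim1`` is the NIfTI x axis (fastest-varying on disk), ``Dim2`` = y,
``Dim3`` = z.  In memory:

* ``time_major``  — ``data[t, z, y, x]`` (acquisition order; time slowest),
* ``voxel_major`` — ``data[z, y, x, t]`` (curve-contiguous; time fastest).

All spatial indices are 0-based.  3D parametric maps produced downstream use
the ``(z, y, x)`` order of ``voxel_major`` data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, DimensionError

__all__ = [
    "Layout",
    "PerfusionSeries",
    "read_series",
    "reorganize",
    "write_map_nifti",
]


class Layout(str, Enum):
    """Physical axis order of a series' data array."""

    TIME_MAJOR = "time_major"
    VOXEL_MAJOR = "voxel_major"


@dataclass
class PerfusionSeries:
    """A 4D perfusion data set plus the grid metadata the pipeline needs.

    Parameters
    ----------
    data
        4D float array; axis order is dictated by ``layout``.
    dims
        Logical sizes ``(Dim1, Dim2, Dim3, Time)`` — x, y, z, time.
    dt
        Sampling interval in seconds (> 0).
    layout
        Which axis order ``data`` is stored in.
    affine
        4x4 voxel-to-world transform carried through from the source image.
    source_dtype
        On-disk numeric type of the source file, for provenance.
    """

    data: np.ndarray
    dims: tuple[int, int, int, int]
    dt: float
    layout: Layout
    affine: np.ndarray
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        self.layout = Layout(self.layout)
        d1, d2, d3, nt = self.dims
        if self.data.ndim != 4:
            raise DimensionError(f"series data must be 4D, got {self.data.ndim}D")
        expected = (nt, d3, d2, d1) if self.layout is Layout.TIME_MAJOR else (d3, d2, d1, nt)
        if self.data.shape != expected:
            raise DimensionError(
                f"data shape {self.data.shape} does not match dims {self.dims} "
                f"under layout {self.layout.value} (expected {expected})"
            )
        if nt < 2:
            raise DimensionError(f"need at least 2 time points, got {nt}")
        if not self.dt > 0:
            raise ConfigurationError(f"sampling interval dt must be > 0, got {self.dt}")

    @property
    def n_time(self) -> int:
        return self.dims[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        """Map/mask shape ``(Dim3, Dim2, Dim1)`` = (z, y, x)."""
        d1, d2, d3, _ = self.dims
        return (d3, d2, d1)

    @property
    def times(self) -> np.ndarray:
        """Sampling times in seconds, ``t_i = i * dt`` starting at 0."""
        return np.arange(self.n_time, dtype=np.float64) * self.dt


def _header_dt_seconds(img: nib.Nifti1Image) -> float | None:
    """Time step from the NIfTI header, converted to seconds, or None."""
    hdr = img.header
    dt = float(hdr["pixdim"][4])
    if dt <= 0:
        return None
    t_unit = hdr.get_xyzt_units()[1]
    if t_unit == "msec":
        return dt / 1000.0
    if t_unit == "usec":
        return dt / 1_000_000.0
    return dt  # 'sec' or unknown: taken as seconds


def read_series(path, dt_override: float | None = None) -> PerfusionSeries:
    """Load a 4D NIfTI-1 perfusion series as a ``time_major`` float64 array.

    NIfTI scl_slope/scl_inter scaling is applied when present (slope != 0), so
    the in-memory values are the physically calibrated ones even when the file
    stores 2-byte integers.  The sampling interval comes from ``dt_override``
    when given, else from the header's 4th pixdim (converted to seconds when
    the header declares msec/usec).

    Raises
    ------
    DimensionError
        If the image is not 4D.
    ConfigurationError
        If no usable sampling interval is available.
    """
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise DimensionError(f"expected a 4D NIfTI volume, got shape {img.shape}")
    if dt_override is not None:
        if not dt_override > 0:
            raise ConfigurationError(f"dt override must be > 0, got {dt_override}")
        dt = float(dt_override)
    else:
        dt = _header_dt_seconds(img)
        if dt is None:
            raise ConfigurationError(
                "no sampling interval: header time step is absent/zero and no "
                "dt override was supplied"
            )
    # get_fdata applies scl_slope/scl_inter when set.
    xyzt = img.get_fdata(dtype=np.float64)
    d1, d2, d3, nt = xyzt.shape
    data = np.ascontiguousarray(xyzt.transpose(3, 2, 1, 0))  # -> [t, z, y, x]
    return PerfusionSeries(
        data=data,
        dims=(d1, d2, d3, nt),
        dt=dt,
        layout=Layout.TIME_MAJOR,
        affine=np.asarray(img.affine, dtype=np.float64),
        source_dtype=img.get_data_dtype(),
    )


def reorganize(series: PerfusionSeries, target_layout: Layout | str) -> PerfusionSeries:
    """Return the series stored in ``target_layout``.

    The value at spatial index (x, y, z) and time t is preserved; only the
    physical storage order changes (``[t,z,y,x]`` <-> ``[z,y,x,t]``).  Calling
    with the current layout returns the series unchanged.
    """
    target = Layout(target_layout)
    if target is series.layout:
        return series
    if target is Layout.VOXEL_MAJOR:  # [t,z,y,x] -> [z,y,x,t]
        data = np.ascontiguousarray(series.data.transpose(1, 2, 3, 0))
    else:  # [z,y,x,t] -> [t,z,y,x]
        data = np.ascontiguousarray(series.data.transpose(3, 0, 1, 2))
    return replace(series, data=data, layout=target)


def write_map_nifti(map3d: np.ndarray, mask: np.ndarray, ref: PerfusionSeries, path) -> None:
    """Write a 3D parametric map as float32 NIfTI on the reference grid.

    ``map3d`` and ``mask`` are in the internal ``(z, y, x)`` order; voxels where
    ``mask`` is False are written as NaN.  The reference series' affine is
    reused so the map overlays the source images.
    """
    if map3d.shape != ref.spatial_shape or mask.shape != ref.spatial_shape:
        raise DimensionError(
            f"map shape {map3d.shape} / mask shape {mask.shape} do not match "
            f"reference spatial shape {ref.spatial_shape}"
        )
    out = np.where(mask, map3d, np.nan).astype(np.float32)
    img = nib.Nifti1Image(np.ascontiguousarray(out.transpose(2, 1, 0)), ref.affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
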