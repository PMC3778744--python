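"""Pipeline orchestration: serial reference engine and chunked parallel engine.

Both engines execute the same stages — reorganise (+ optional denoise), mask,
optional baseline correction, AIF selection, voxel-wise truncated-SVD
deconvolution, map assembly — and are guaranteed to produce *bit-identical*
outputs.  The guarantee is structural: each voxel's result is computed by the
same function with the same floating-point operation sequence in both engines;
there are no cross-voxel reductions, so scheduling (which worker handles which
chunk, in which order) cannot change any output bit.

The parallel engine partitions voxels into chunks (default: one axial slice
per chunk), dispatches them to a thread pool, and has each worker reuse one
preallocated deconvolution workspace across all voxels it processes — the
scratch buffers are allocated once per worker, not once per voxel.  Workers
write into disjoint indices of preallocated output volumes.

In global-AIF (or file-AIF) mode the pseudoinverse is computed exactly once
and shared read-only by every voxel; in local-AIF mode each voxel selects its
neighbourhood AIF and factorises its own matrix, which is the expensive
clinical configuration the chunked engine exists for.
"""

from __future__ import annotations

import logging
import queue
import time as _time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import aif as aif_mod
from . import decon as decon_mod
from .errors import ConfigurationError, DimensionError
from .maps import (
    DEFAULT_RISE_FRAC,
    ParametricMaps,
    compute_scalar_maps,
    compute_timing_maps,
)
from .preprocess import KernelSpec, baseline_correct, compute_brain_mask, denoise_weighted_mean
from .series_io import Layout, PerfusionSeries, reorganize

__all__ = ["RunConfig", "Workspace", "run_serial", "run_parallel"]

logger = logging.getLogger("perfquant")

AIF_MODES = ("global", "local", "file")


@dataclass
class RunConfig:
    """All tunables of one pipeline run."""

    dt: float | None = None  # override; None = use the series' dt
    svd_rel_threshold: float = decon_mod.DEFAULT_REL_THRESHOLD
    aif_mode: str = "global"
    aif_vector: aif_mod.AIFVector | None = None  # required for aif_mode="file"
    global_top_k: int = 5
    local_radius: int = 5
    local_top_k: int = 5
    denoise: KernelSpec | None = None
    baseline_frames: int | None = None
    mask_frac: float = 0.15
    workers: int = 1
    chunk: str | int = "slice"  # "slice" or a voxel count per chunk
    seed: int = 0  # carried for provenance; the engines draw no randomness
    lo_pct: float = 2.0
    hi_pct: float = 98.0
    rise_frac: float = DEFAULT_RISE_FRAC

    def validate(self) -> None:
        if self.aif_mode not in AIF_MODES:
            raise ConfigurationError(f"aif_mode must be one of {AIF_MODES}")
        if self.aif_mode == "file" and self.aif_vector is None:
            raise ConfigurationError("aif_mode='file' requires aif_vector")
        if not 0 <= self.svd_rel_threshold < 1:
            raise ConfigurationError("svd_rel_threshold must be in [0, 1)")
        if self.workers < 1:
            raise ConfigurationError("workers must be >= 1")
        if isinstance(self.chunk, int) and self.chunk < 1:
            raise ConfigurationError("chunk voxel count must be >= 1")
        if isinstance(self.chunk, str) and self.chunk != "slice":
            raise ConfigurationError("chunk must be 'slice' or a voxel count")


class Workspace:
    """Per-worker reusable deconvolution scratch space.

    Holds the length-Time impulse-response buffer the matrix-vector product
    writes into; allocated once per worker and reused for every voxel that
    worker processes.
    """

    def __init__(self, n_time: int):
        self.h = np.empty(n_time, dtype=np.float64)


@dataclass
class _Prepared:
    """Everything the per-voxel loop needs, identical for both engines."""

    data: np.ndarray  # voxel_major (z, y, x, t), post-preprocessing
    mask: np.ndarray
    dt: float
    rise_frac: float
    rel_threshold: float
    aif_mode: str
    global_pinv: np.ndarray | None
    fallback_aif: aif_mod.AIFVector | None
    series: PerfusionSeries  # voxel_major, post-preprocessing
    config: RunConfig
    timings: dict = field(default_factory=dict)


def _prepare(series: PerfusionSeries, config: RunConfig) -> _Prepared:
    config.validate()
    dt = config.dt if config.dt is not None else series.dt
    if not dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    timings: dict[str, float] = {}

    t0 = _time.perf_counter()
    vox = reorganize(series, Layout.VOXEL_MAJOR)
    if vox.dt != dt:
        from dataclasses import replace

        vox = replace(vox, dt=dt)
    if config.denoise is not None:
        vox = denoise_weighted_mean(vox, config.denoise)
    timings["reorganize_denoise"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    mask = compute_brain_mask(vox, config.mask_frac)
    if config.baseline_frames is not None:
        vox = baseline_correct(vox, config.baseline_frames)
    timings["mask_baseline"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    nt = vox.n_time
    global_pinv = None
    fallback = None
    if not mask.any():
        # nothing to deconvolve (e.g. an all-zero volume): every voxel invalid
        pass
    elif config.aif_mode == "file":
        aifv = config.aif_vector
        if len(aifv) != nt:
            raise DimensionError(
                f"supplied AIF has {len(aifv)} samples but the series has "
                f"Time={nt} time points"
            )
        ca = aif_mod.build_aif_matrix(aif_mod.AIFVector(aifv.values, dt))
        global_pinv = decon_mod.truncated_pseudoinverse(ca, config.svd_rel_threshold)
    elif config.aif_mode == "global":
        aifv = aif_mod.select_global_aif(vox, mask, config.global_top_k)
        ca = aif_mod.build_aif_matrix(aifv)
        global_pinv = decon_mod.truncated_pseudoinverse(ca, config.svd_rel_threshold)
    else:  # local: per-voxel AIF, with the global one as fallback
        fallback = aif_mod.select_global_aif(vox, mask, config.global_top_k)
    timings["aif"] = _time.perf_counter() - t0

    return _Prepared(
        data=vox.data,
        mask=mask,
        dt=dt,
        rise_frac=config.rise_frac,
        rel_threshold=config.svd_rel_threshold,
        aif_mode=config.aif_mode,
        global_pinv=global_pinv,
        fallback_aif=fallback,
        series=vox,
        config=config,
        timings=timings,
    )


def _alloc_outputs(shape3) -> ParametricMaps:
    return ParametricMaps(
        cbf=np.full(shape3, np.nan),
        cbv=np.full(shape3, np.nan),
        mtt=np.full(shape3, np.nan),
        ttp=np.full(shape3, np.nan),
        ta=np.full(shape3, np.nan),
        valid=np.zeros(shape3, dtype=bool),
    )


def _process_chunk(prep: _Prepared, out: ParametricMaps, ws: Workspace,
                   flat_indices: np.ndarray) -> None:
    """Deconvolve every in-mask voxel of one chunk, writing results in place.

    This is the single per-voxel code path shared by both engines; the chunk is
    a list of flat (z-major) voxel indices.
    """
    nz, ny, nx = prep.mask.shape
    data2d = prep.data.reshape(-1, prep.data.shape[-1])
    mask_flat = prep.mask.ravel()
    cfg = prep.config
    for fi in flat_indices:
        if not mask_flat[fi]:
            continue
        ct = data2d[fi]
        if prep.aif_mode == "local":
            z, rem = divmod(int(fi), ny * nx)
            y, x = divmod(rem, nx)
            aifv = aif_mod.generate_local_aif(
                prep.series, (x, y, z), cfg.local_radius, cfg.local_top_k,
                prep.fallback_aif, mask=prep.mask,
            )
            ca = aif_mod.build_aif_matrix(aifv)
            pinv = decon_mod.truncated_pseudoinverse(ca, prep.rel_threshold)
        else:
            pinv = prep.global_pinv
        np.matmul(pinv, ct, out=ws.h)
        scal = compute_scalar_maps(ws.h, prep.dt)
        idx = np.unravel_index(fi, prep.mask.shape)
        if scal is None:
            continue  # stays NaN / invalid
        ttp, ta = compute_timing_maps(ct, prep.dt, prep.rise_frac)
        out.cbf[idx], out.cbv[idx], out.mtt[idx] = scal
        out.ttp[idx], out.ta[idx] = ttp, ta
        out.valid[idx] = True


def _chunks(prep: _Prepared, chunk: str | int) -> list[np.ndarray]:
    """Partition all flat voxel indices (ascending z-major order) into chunks."""
    nz, ny, nx = prep.mask.shape
    all_idx = np.arange(nz * ny * nx, dtype=np.intp)
    if chunk == "slice":
        per = ny * nx
        return [all_idx[z * per : (z + 1) * per] for z in range(nz)]
    k = int(chunk)
    return [all_idx[i : i + k] for i in range(0, all_idx.size, k)]


def run_serial(series: PerfusionSeries, config: RunConfig) -> ParametricMaps:
    """Reference engine: one workspace, all voxels in ascending index order."""
    prep = _prepare(series, config)
    out = _alloc_outputs(prep.mask.shape)
    ws = Workspace(prep.data.shape[-1])
    t0 = _time.perf_counter()
    for chunk in _chunks(prep, "slice"):
        _process_chunk(prep, out, ws, chunk)
    prep.timings["deconvolve"] = _time.perf_counter() - t0
    _log_timings("serial", prep.timings, out)
    return out


def run_parallel(series: PerfusionSeries, config: RunConfig) -> ParametricMaps:
    """Chunked worker-pool engine; output bit-identical to :func:`run_serial`.

    Voxel chunks are dispatched to ``config.workers`` threads.  Each worker
    borrows one reusable :class:`Workspace` from a pool of exactly ``workers``
    workspaces for the duration of a chunk, and results go straight into the
    shared preallocated output volumes at each voxel's global index.
    """
    prep = _prepare(series, config)
    out = _alloc_outputs(prep.mask.shape)
    chunks = _chunks(prep, config.chunk)
    ws_pool: queue.SimpleQueue[Workspace] = queue.SimpleQueue()
    for _ in range(config.workers):
        ws_pool.put(Workspace(prep.data.shape[-1]))

    def worker(chunk: np.ndarray) -> None:
        ws = ws_pool.get()
        try:
            _process_chunk(prep, out, ws, chunk)
        finally:
            ws_pool.put(ws)

    t0 = _time.perf_counter()
    with ThreadPoolExecutor(max_workers=config.workers) as pool:
        list(pool.map(worker, chunks))
    prep.timings["deconvolve"] = _time.perf_counter() - t0
    _log_timings(f"parallel[{config.workers}w]", prep.timings, out)
    return out


def _log_timings(tag: str, timings: dict, out: ParametricMaps) -> None:
    stages = " ".join(f"{k}={v:.3f}s" for k, v in timings.items())
    logger.info("%s: %s valid_voxels=%d", tag, stages, int(out.valid.sum()))
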