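"""Digital perfusion phantoms with exact ground truth.

A phantom is a 4D bolus-passage series built from first principles:

* the arterial signal is a gamma-variate bolus
  ``Ca(t) = A·(t - t0)^alpha · exp(-(t - t0)/beta)`` for t > t0 — the standard
  parametric model of a first-pass contrast bolus — scaled to vessel-like
  amplitude;
* each tissue region has an exponential residue function
  ``h(t) = cbf · exp(-(t - delay)/mtt)`` (zero before ``delay``), the simplest
  physiologically standard model of contrast washout;
* tissue curves are the *discrete* forward convolution ``Ca_mat · h`` using the
  very same dt-scaled Toeplitz operator the deconvolution stage inverts, so a
  noise-free phantom deconvolved at threshold 0 is an exact round trip — a true
  oracle, not an approximation claim;
* optional i.i.d. Gaussian noise (seeded) and a constant baseline are added on
  top, emulating the additive-noise term of the measurement model.

There is a single effective AIF: the arterial-region signal itself.  It is
written into the arterial voxels, used as the forward operator for every
tissue curve, and recorded as ``PhantomTruth.aif`` — so a pipeline run that
selects its global AIF from the phantom's arterial voxels deconvolves with
exactly the operator that generated the data.

Ground truth is likewise discrete: ``truth.cbv = dt·Σ h_true`` and
``truth.mtt = cbv/cbf``, which is what an exact inverse can recover; the
nominal continuous-time mtt of each region and the resulting rectangle-rule
correction factor are recorded in ``truth.meta``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .aif import AIFVector, build_aif_matrix
from .errors import ConfigurationError, DimensionError
from .series_io import Layout, PerfusionSeries, write_map_nifti

__all__ = [
    "GammaParams",
    "Region",
    "PhantomSpec",
    "PhantomTruth",
    "gamma_variate_aif",
    "residue_curve",
    "simulate_voxel_curve",
    "build_phantom",
    "preset_spec",
    "write_phantom",
    "PRESETS",
]

AIF_FLOOR_FRAC = 1e-6  # floor on Ca(t1), keeps the Toeplitz operator invertible

# Mask fraction suited to phantoms: their background is exactly zero (plus
# noise), while the clinical default of 0.15 assumes tissue intensities within
# an order of magnitude of the brightest voxel.  Phantom vessels are ~30x
# brighter than tissue, so a much lower relative cut keeps all tissue in-mask.
PHANTOM_MASK_FRAC = 0.01


@dataclass
class GammaParams:
    """Gamma-variate bolus parameters: amplitude, arrival t0 (s), shape, scale (s)."""

    amplitude: float = 1.0
    t0: float = 0.0
    alpha: float = 3.0
    beta: float = 1.5

    @property
    def peak_time(self) -> float:
        """Time of the bolus maximum, t0 + alpha*beta."""
        return self.t0 + self.alpha * self.beta


@dataclass
class Region:
    """A box-shaped tissue compartment with uniform perfusion parameters.

    ``box`` is half-open voxel ranges ``((x0, x1), (y0, y1), (z0, z1))``.
    ``cbf`` is the residue amplitude (IRF units), ``mtt`` the washout time
    constant in seconds, ``delay`` the extra bolus delay of this tissue in
    seconds (ideally a multiple of dt so arrival lands on the grid).
    """

    label: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    cbf: float
    mtt: float
    delay: float = 0.0


@dataclass
class PhantomSpec:
    """Generative parameters of a phantom; the defaults are the tiny preset."""

    dims: tuple[int, int, int, int] = (16, 16, 2, 40)
    dt: float = 1.5
    aif_params: GammaParams = field(default_factory=GammaParams)
    regions: list[Region] = field(default_factory=list)
    arterial_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (6, 10),
        (0, 1),
        (0, 2),
    )
    arterial_scale: float = 3.0
    noise_sigma: float = 0.0
    noise_frac_of_peak: float | None = None
    baseline: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        d1, d2, d3, nt = self.dims
        if min(d1, d2, d3) < 1 or nt < 2:
            raise ConfigurationError(f"bad phantom dims {self.dims}")
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        p = self.aif_params
        if min(p.amplitude, p.alpha, p.beta) <= 0:
            raise ConfigurationError("gamma-variate amplitude/alpha/beta must be > 0")
        if not nt * self.dt > p.peak_time:
            raise ConfigurationError(
                f"bolus peak at {p.peak_time}s falls outside the {nt * self.dt}s window"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        boxes = [r.box for r in self.regions] + [self.arterial_box]
        occupancy = np.zeros((d3, d2, d1), dtype=np.int32)
        for (x0, x1), (y0, y1), (z0, z1) in boxes:
            if not (0 <= x0 < x1 <= d1 and 0 <= y0 < y1 <= d2 and 0 <= z0 < z1 <= d3):
                raise ConfigurationError(f"box {((x0, x1), (y0, y1), (z0, z1))} outside volume")
            occupancy[z0:z1, y0:y1, x0:x1] += 1
        if occupancy.max() > 1:
            raise ConfigurationError("phantom regions overlap")
        for r in self.regions:
            if r.cbf <= 0 or r.mtt <= 0:
                raise ConfigurationError(f"region {r.label}: cbf and mtt must be > 0")


@dataclass
class PhantomTruth:
    """Ground-truth maps (z, y, x; NaN outside tissue regions) and the AIF."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ta: np.ndarray
    aif: AIFVector
    meta: dict = field(default_factory=dict)


def gamma_variate_aif(params: GammaParams, times: np.ndarray) -> AIFVector:
    """Sample the gamma-variate bolus on a time grid.

    Zero for t <= t0.  The first sample is floored at ``1e-6 * amplitude`` so
    the Toeplitz convolution matrix built from the curve stays invertible.
    """
    if min(params.amplitude, params.alpha, params.beta) <= 0:
        raise ConfigurationError("gamma-variate amplitude/alpha/beta must be > 0")
    times = np.asarray(times, dtype=np.float64)
    if times.size < 2:
        raise DimensionError("need at least 2 time samples")
    tau = times - params.t0
    values = np.zeros_like(times)
    pos = tau > 0
    values[pos] = params.amplitude * tau[pos] ** params.alpha * np.exp(-tau[pos] / params.beta)
    if values[0] <= 0.0:
        values[0] = AIF_FLOOR_FRAC * params.amplitude
    return AIFVector(values, float(times[1] - times[0]))


def residue_curve(times: np.ndarray, cbf: float, mtt: float, delay: float = 0.0) -> np.ndarray:
    """Delayed exponential residue: cbf*exp(-(t-delay)/mtt) for t >= delay, else 0."""
    times = np.asarray(times, dtype=np.float64)
    tau = times - delay
    h = np.zeros_like(times)
    on = tau >= 0
    h[on] = cbf * np.exp(-tau[on] / mtt)
    return h


def simulate_voxel_curve(
    aif: AIFVector,
    cbf: float,
    mtt: float,
    delay: float = 0.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One tissue curve: discrete forward convolution of the AIF with a residue.

    ``Ct = Ca_mat · h_true + eps`` with eps i.i.d. Gaussian(0, noise_sigma²)
    from ``rng``.  Uses the same discretisation the deconvolution stage
    inverts, so at noise 0 the curve is exactly recoverable.
    """
    if cbf <= 0 or mtt <= 0:
        raise ConfigurationError("cbf and mtt must be > 0")
    times = np.arange(len(aif), dtype=np.float64) * aif.dt
    h = residue_curve(times, cbf, mtt, delay)
    ct = build_aif_matrix(aif).matrix @ h
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        ct = ct + rng.normal(0.0, noise_sigma, size=ct.shape)
    return ct


def _box_slices(box):
    (x0, x1), (y0, y1), (z0, z1) = box
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1))


def build_phantom(spec: PhantomSpec) -> tuple[PerfusionSeries, PhantomTruth]:
    """Generate the 4D series and its ground truth from a phantom spec.

    Returns a ``time_major`` series (as a scanner would deliver it) and the
    discrete ground-truth maps.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    d1, d2, d3, nt = spec.dims
    dt = spec.dt
    # Acquisition grid: frame i is acquired at t_i = (i+1)*dt after injection
    # (the 1-based sampling t1..tN with t1 = dt).  With the default t0 = 0 the
    # first AIF sample already sits on the rising bolus, so the Toeplitz
    # operator — whose entire main diagonal is dt*Ca(t1) — is comfortably
    # invertible and the noise-free phantom is exactly recoverable.  The
    # residue function lives on the lag grid tau_j = j*dt starting at 0.
    aif_times = (np.arange(nt, dtype=np.float64) + 1.0) * dt
    lag_times = np.arange(nt, dtype=np.float64) * dt
    base = gamma_variate_aif(spec.aif_params, aif_times)
    # the one effective AIF: vessel-amplitude bolus, floored for invertibility
    aif_values = spec.arterial_scale * base.values
    aif = AIFVector(aif_values, dt)
    ca_mat = build_aif_matrix(aif).matrix

    vol = np.full((nt, d3, d2, d1), float(spec.baseline), dtype=np.float64)
    shape3 = (d3, d2, d1)
    truth_cbf = np.full(shape3, np.nan)
    truth_cbv = np.full(shape3, np.nan)
    truth_mtt = np.full(shape3, np.nan)
    truth_ta = np.full(shape3, np.nan)

    zz, yy, xx = _box_slices(spec.arterial_box)
    vol[:, zz, yy, xx] += aif_values[:, None, None, None]

    region_meta = {}
    tissue_peak = 0.0
    for r in spec.regions:
        h = residue_curve(lag_times, r.cbf, r.mtt, r.delay)
        ct = ca_mat @ h
        tissue_peak = max(tissue_peak, float(ct.max()))
        zz, yy, xx = _box_slices(r.box)
        vol[:, zz, yy, xx] += ct[:, None, None, None]
        cbv = float(dt * h.sum())
        sl3 = _box_slices(r.box)
        truth_cbf[sl3] = r.cbf
        truth_cbv[sl3] = cbv
        truth_mtt[sl3] = cbv / r.cbf
        truth_ta[sl3] = spec.aif_params.t0 + r.delay
        region_meta[r.label] = {
            "cbf": r.cbf,
            "mtt_nominal": r.mtt,
            "mtt_discrete": cbv / r.cbf,
            "cbv_discrete": cbv,
            "discrete_correction": cbv / (r.cbf * r.mtt),
            "delay": r.delay,
            "n_voxels": int(np.prod([hi - lo for lo, hi in r.box])),
        }

    sigma = spec.noise_sigma
    if spec.noise_frac_of_peak is not None:
        if not spec.regions:
            raise ConfigurationError("noise_frac_of_peak needs at least one tissue region")
        sigma = spec.noise_frac_of_peak * tissue_peak
    rng = np.random.default_rng(spec.seed)
    if sigma > 0:
        vol += rng.normal(0.0, sigma, size=vol.shape)

    series = PerfusionSeries(
        data=vol,
        dims=spec.dims,
        dt=dt,
        layout=Layout.TIME_MAJOR,
        affine=np.eye(4),
        source_dtype=np.dtype(np.float64),
    )
    truth = PhantomTruth(
        cbf=truth_cbf,
        cbv=truth_cbv,
        mtt=truth_mtt,
        ta=truth_ta,
        aif=aif,
        meta={
            "noise_sigma": float(sigma),
            "tissue_peak": tissue_peak,
            "regions": region_meta,
            "seed": spec.seed,
        },
    )
    return series, truth


def _standard_regions(d1: int, d2: int, d3: int, dt: float) -> tuple[list[Region], tuple]:
    """Two tissue slabs (CBF ratio 2:1, the second delayed) plus an arterial strip.

    CBF values are physiological in IRF-amplitude units (h in 1/s): gray-matter
    flow of ~60 ml/100g/min is ~0.01 1/s; white matter half that.  With mtt of
    4 s and 6 s the implied blood volumes are 4% and 3%.  At these amplitudes
    arterial curves tower over tissue curves, as in real scans, so the
    high-early-peak AIF selection criterion has a wide margin.
    """
    xa0, xa1 = d1 // 2 - 2, d1 // 2 + 2
    arterial = ((xa0, xa1), (0, 1), (0, d3))
    mid = d2 // 2
    regions = [
        Region("gray", ((1, d1 - 1), (1, mid), (0, d3)), cbf=0.010, mtt=4.0, delay=0.0),
        Region("white", ((1, d1 - 1), (mid, d2 - 1), (0, d3)), cbf=0.005, mtt=6.0, delay=2 * dt),
    ]
    return regions, arterial


PRESETS = ("tiny", "mr-paper", "ct-paper")


def preset_spec(
    name: str,
    seed: int = 0,
    noise_frac_of_peak: float | None = None,
) -> PhantomSpec:
    """Named phantom configurations.

    ``tiny`` (16x16x2x40) runs the whole pipeline in well under a second and is
    the default test fixture; ``mr-paper`` (128x128x22x80) and ``ct-paper``
    (128x128x11x44) reproduce the standard MR/CT perfusion acquisition sizes
    for scale testing.
    """
    sizes = {
        "tiny": (16, 16, 2, 40),
        "mr-paper": (128, 128, 22, 80),
        "ct-paper": (128, 128, 11, 44),
    }
    if name not in sizes:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(sizes)}")
    d1, d2, d3, nt = sizes[name]
    dt = 1.5
    regions, arterial = _standard_regions(d1, d2, d3, dt)
    return PhantomSpec(
        dims=(d1, d2, d3, nt),
        dt=dt,
        regions=regions,
        arterial_box=arterial,
        seed=seed,
        noise_frac_of_peak=noise_frac_of_peak,
    )


def write_phantom(spec: PhantomSpec, out_dir) -> dict:
    """Materialise a phantom: series + truth NIfTIs, AIF text, resolved spec JSON.

    Returns the paths written, keyed by artifact name.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth = build_phantom(spec)
    paths = {}

    import nibabel as nib

    xyzt = np.ascontiguousarray(series.data.transpose(3, 2, 1, 0))
    img = nib.Nifti1Image(xyzt.astype(np.float32), series.affine)
    img.header.set_xyzt_units("mm", "sec")
    img.header["pixdim"][4] = spec.dt
    paths["series"] = out / "phantom.nii.gz"
    nib.save(img, str(paths["series"]))

    finite_any = np.isfinite(truth.cbf)
    for key, arr in (("cbf", truth.cbf), ("cbv", truth.cbv),
                     ("mtt", truth.mtt), ("ta", truth.ta)):
        paths[f"truth_{key}"] = out / f"truth_{key}.nii.gz"
        write_map_nifti(np.nan_to_num(arr, nan=0.0), finite_any, series, paths[f"truth_{key}"])

    paths["aif"] = out / "aif.txt"
    np.savetxt(paths["aif"], truth.aif.values, fmt="%.10g")

    spec_dict = asdict(spec)
    paths["spec"] = out / "phantom_spec.json"
    paths["spec"].write_text(json.dumps(spec_dict, indent=2, default=float) + "\n")
    return paths
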