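# Methods

## Measurement model and deconvolution

A perfusion acquisition samples each voxel's contrast concentration at N time
points spaced Δt seconds apart. The tissue curve is modelled as

    C_t = Ca · h + ε,

where Ca is the Δt-scaled lower-triangular Toeplitz matrix built from the
arterial input function (entry (i, j) = Δt·C_a(t_{i−j+1}) for i ≥ j) and h is
the impulse-response (residue) function. Because the AIF is smooth, the rows
of Ca are nearly linearly dependent: the inversion is ill-posed, and its
conditioning worsens as N grows (the test suite asserts cond(80-point) >
cond(20-point) for the same bolus shape). The solver therefore computes a
truncated-SVD pseudoinverse: Ca = U·diag(w)·Vᵀ, every singular value with
w_i < τ·w_max is zeroed (strict inequality — boundary values are kept), and

    Ca⁺ = V · diag(1/w_i or 0) · Uᵀ,      h = Ca⁺ · C_t.

The threshold τ is *relative* to the largest singular value, making the rule
invariant under rescaling of the AIF (arbitrary units are ubiquitous in
perfusion data). The default τ = 0.2 is the value commonly used with SVD
deconvolution in the perfusion literature; τ = 0 reproduces the exact inverse
for invertible systems and is used by the exactness tests. At τ = 0.2 and the
default phantom's 40-point bolus, 14 of 40 singular values survive.

Per AIF, the pseudoinverse is computed once and reused for every voxel that
shares it: one SVD per run in global/file mode, one per voxel in local mode
(the expensive clinical configuration).

## Parameter maps

From each voxel's recovered response and curve:

* CBF = max_t h(t) — the response amplitude (units: 1/s when concentration
  units cancel; the package reports "IRF-amplitude units" and makes no
  ml/100g/min calibration, which would need density and hematocrit constants
  outside its scope).
* CBV = Δt·Σ_t max(h(t), 0) — rectangle-rule integral. Negative lobes are
  truncation ringing, not physiology; they are clipped in the sum only, so
  CBV stays positive without touching the peak that defines CBF. The Δt
  factor keeps CBV invariant under temporal resampling.
* MTT = CBV/CBF, the central volume theorem. (Stated inversions of this
  ratio occasionally appear in the literature as typographical slips; the
  central volume theorem fixes the orientation: mean transit time is
  volume over flow.)
* TTP = Δt·argmax C_t (first maximum on ties); TA = Δt·(first index with
  C_t ≥ 0.1·max C_t). The 10% rise fraction is configurable; pure-noise
  curves (max ≤ 0) get NaN.

A voxel is *valid* when CBF > 0 and CBV > 0; invalid voxels are NaN in all
five maps. Rendered images window valid values to the [2, 98] percentile
range of the valid voxels, map linearly onto a fixed 256-entry
blue→cyan→green→yellow→red lookup table, and paint invalid voxels black.

## Pipeline stages and engines

Stages run in a fixed order: load → reorganise (+ optional denoise) → mask →
optional baseline subtraction → AIF selection → per-voxel deconvolution →
map assembly. Data arrive time-major ([t][z][y][x], the scanner/file order)
and are transposed to voxel-major ([z][y][x][t]) so each voxel's curve is
contiguous — the per-voxel stage is memory-bound without this.

The weighted-mean denoiser exploits spatial continuity of perfusion (blood
flows between neighbours). Kernels are 2D (in-slice), 3D (spatial) or 4D
(spatial+time), default uniform with radius 1; the border policy is
truncate-and-renormalise, chosen over zero padding because padding darkens
edges. The paper-trail for kernel weights in the field is thin; uniform
radius-1 is a deliberate, replaceable default. Denoising, baseline
subtraction and masking are all off by default: input series are assumed to
already be concentration curves.

Brain masking thresholds time-averaged intensity at a fraction of the volume
maximum (default 0.15 for clinical data, where brain tissue is within an
order of magnitude of the brightest voxel). Digital phantoms have exactly
zero background and vessels ~30× brighter than tissue, so phantom runs use
0.01 (`PHANTOM_MASK_FRAC`); this is a property of the phantom's contrast
range, not a tuning knob.

AIF selection scores every in-mask curve by peak/(1 + time-to-peak index) —
"high and early", the two properties arterial voxels have — and averages the
top-k (default 5) by (score desc, voxel index asc), the deterministic
tie-break the identity contract needs. The average is computed as pivot +
mean of deviations from the best curve, which avoids cancellation and makes
the mean of k identical curves bitwise equal to the curve. Local AIFs apply
the same scoring inside a cube of side 2·radius+1 (default radius 5) and
fall back to the global AIF when fewer than k candidates have positive
peaks. The score is a documented default, not a claim of optimality; an
externally measured AIF bypasses selection entirely.

**Serial/parallel identity.** The parallel engine partitions voxels into
chunks (default one axial slice; any voxel count works, divisor or not),
dispatches chunks to a thread pool, and writes results into preallocated
output volumes at each voxel's global index. Each worker borrows one
reusable workspace (the length-N response buffer) allocated once per worker.
Identity with the serial engine is structural, not statistical: both engines
execute the same per-voxel function with the same floating-point sequence,
there are no cross-voxel reductions, and scheduling only permutes *which*
disjoint outputs are written when. The test suite asserts bitwise equality
across worker counts and chunk sizes, on noisy data, in both global and
local AIF modes. Threads (not processes) are used because the per-voxel
work is LAPACK/BLAS calls that release the GIL, and shared output arrays
make in-place result collection trivial.

All computation is float64 from load to map assembly; maps are written as
float32 NIfTI (with the source affine) — the identity contract is defined on
the float64 in-memory results.

## The digital phantom

The generator emulates a first-pass bolus acquisition:

* **AIF**: gamma-variate bolus A·(t−t0)^α·e^(−(t−t0)/β), defaults α = 3,
  β = 1.5 s, t0 = 0, scaled ×3 to vessel-like amplitude. The first sample is
  floored at 1e-6·A if nonpositive so the Toeplitz operator is formally
  invertible.
* **Sampling grid**: frame i is acquired at t_i = (i+1)·Δt after injection
  (1-based sampling, t1 = Δt). This is deliberate: the entire main diagonal
  of the Toeplitz operator equals Δt·C_a(t1), so if the first sample sat in
  the pre-bolus zeros the operator would be numerically singular
  (condition number ~1e24) and no exact-recovery statement could be made in
  float64. With t1 on the rising bolus the condition number is ~2e7 and the
  noise-free round trip is exact to ~1e-9.
* **Tissue**: each box region has an exponential residue
  h(t) = CBF·e^(−(t−delay)/MTT) (zero before its delay), the simplest
  standard washout model. Defaults are physiological in IRF-amplitude
  units: gray 0.010 s⁻¹/4 s, white 0.005 s⁻¹/6 s (CBF ratio 2:1, implied
  CBV 4%/3%), the white-matter bolus delayed 2 frames.
* **Forward model**: tissue curves are Ca_mat·h with the *same* discrete
  operator the solver inverts, and there is a single effective AIF — the
  arterial-region signal itself is the forward operator and the recorded
  ground-truth AIF. Consequently a global-AIF pipeline run selects exactly
  the operator that generated the data, and the noise-free round trip is a
  true oracle rather than an approximation claim. Ground truth is likewise
  discrete: truth CBV = Δt·Σh and truth MTT = CBV/CBF; the nominal
  continuous-time MTT and the rectangle-rule correction factor
  (≈1.19 at Δt/MTT = 0.375) are recorded in the truth metadata.
* **Noise**: i.i.d. additive Gaussian, seeded (bitwise-reproducible).
  `noise_frac_of_peak` sets σ relative to the peak noise-free tissue signal;
  the validation runs use 5%.
* **Presets**: `tiny` (16×16×2×40, the default test size — the whole suite
  runs in seconds), `mr-paper` (128×128×22×80) and `ct-paper`
  (128×128×11×44), the standard MR/CT perfusion acquisition sizes, used for
  scale testing.

What the phantom does *not* emulate: vascular geometry and partial-volume
mixing, signal→concentration nonlinearity, recirculation, motion, scanner
drift, or spatially correlated noise. Passing the phantom tests therefore
demonstrates correctness of the discrete quantification chain — operator
construction, truncation, inversion, map formulas, scheduling — not clinical
accuracy on real scans, where AIF partial volume and delay/dispersion are
known confounders and are out of scope here.

## Numerical choices and degenerate inputs

* Truncation comparison is strict (w < τ·w_max dropped); ties kept.
* Argmax ties (TTP, CBF) resolve to the first occurrence.
* A zero or all-negative response, or an empty mask (e.g. an all-zero
  volume), yields invalid voxels/empty output rather than an error; a zero
  AIF matrix raises a configuration error.
* Rendering a constant map (degenerate percentile window) maps to LUT
  index 0 by convention.
* dt precedence: explicit override > NIfTI header (msec/usec converted to
  seconds); absent both, loading fails with a configuration error.
* NIfTI scl_slope/scl_inter are honoured when slope ≠ 0. Dim1 is mapped to
  NIfTI x (fastest on disk), Dim3 to z.

## Validation quantities

Measured by `scripts/acceptance.py` (and mirrored in the test suite) at
seed 1: noise-free round-trip max relative error ~2e-14 (CBF) / ~3e-10
(CBV, MTT) over 392 tissue voxels; truncated-SVD vs direct-inverse max
relative discrepancy ~7e-13 over 200 random systems (sizes 4–44, leading
sample dominant — well-conditioned by construction; far from that regime
triangular-Toeplitz inverses grow exponentially and *no* algorithm agrees to
1e-8 in float64); serial-vs-parallel divergence exactly 0.0; median relative
CBF error at 5% noise ≈ 2.5e5 unregularised vs ≈ 0.15 at τ = 0.2; the
mr-paper-size run quantifies 100% of tissue voxels in well under a minute
and ~0.8 GB. The tiny phantom sizes were chosen so the full suite runs in
seconds; the scale run uses the full 128×128×22×80 grid.
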