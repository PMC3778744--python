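# perfquant

Brain perfusion quantification by truncated-SVD deconvolution.

`perfquant` turns a 4D CT or MR bolus-passage acquisition into the parametric
maps used in acute-stroke and tumour imaging: **CBF** (cerebral blood flow),
**CBV** (cerebral blood volume), **MTT** (mean transit time), **TTP** (time to
peak) and **TA** (time of contrast arrival). It is written for image-analysis
engineers and researchers who need a transparent, testable reference
implementation: a serial engine, a chunked worker-pool engine guaranteed to
produce *bit-identical* results, and a built-in digital phantom generator with
exact ground truth so every stage can be validated without patient data.

## The model

Each voxel's tissue concentration curve C_t is modelled as the convolution of
an arterial input function (AIF) C_a with the tissue impulse-response
(residue) function h, plus noise:

    C_t = C_a ⊗ h + ε

Discretised on the acquisition grid, the convolution operator is the
Δt-scaled lower-triangular Toeplitz matrix

    Ca[i, j] = Δt · C_a(t_{i−j+1})   for i ≥ j,   0 otherwise,

and the deconvolution h = Ca⁻¹ · C_t is regularised by **truncated SVD**:
factor Ca = U·W·Vᵀ, zero every singular value below a relative threshold
(default 0.2 of the largest), and pseudoinvert the rest. Truncation is
essential — the rows of Ca are near-linear combinations of each other, so the
problem is ill-posed and unregularised inversion amplifies measurement noise
catastrophically. From the recovered response:

    CBF = max_t h(t)        CBV = Δt · Σ_t max(h(t), 0)        MTT = CBV / CBF

with MTT = CBV/CBF by the central volume theorem. TTP and TA come from the
concentration curve itself (time of its maximum; first time it reaches 10% of
its maximum). The AIF can be global (selected automatically from the
highest/earliest-peaking voxel curves), local (selected per voxel from a
cubic neighbourhood, which tolerates the regionally delayed contrast arrival
seen in stroke), or supplied externally as a text vector.

## Worked example

Generate a small digital phantom and quantify it:

```sh
perfquant simulate --preset tiny --out-dir phantom --seed 3
perfquant run --input phantom/phantom.nii.gz --output-dir maps \
    --mask-frac 0.01 --workers 2
```

which prints

```
phantom written: phantom/phantom.nii.gz, phantom/truth_cbf.nii.gz, ...
wrote 5 maps to maps (400/512 valid voxels)
```

The phantom is a 16×16×2 volume with 40 frames at Δt = 1.5 s: an arterial
strip carrying a gamma-variate bolus, a "gray matter" slab (CBF 0.010 s⁻¹,
MTT 4 s), and a "white matter" slab (CBF 0.005 s⁻¹, MTT 6 s, bolus delayed by
3 s). 400 of the 512 voxels carry signal (392 tissue + 8 arterial); the rest
are background and are excluded by the brain mask (`--mask-frac 0.01` is
appropriate for a zero-background phantom; clinical data typically uses the
0.15 default). `maps/` then contains `cbf.nii.gz` … `ta.nii.gz`, one PNG
rendering per slice per parameter, and `report.json` with the fully resolved
configuration. On the noise-free phantom at `--svd-threshold 0`, recovered
CBF/CBV/MTT match the generator's ground truth to better than 1e-9 relative;
at the default threshold 0.2 a deliberate truncation bias appears — the price
of noise robustness on real data.

The same thing in Python:

```python
from perfquant import RunConfig, run_parallel, build_phantom, preset_spec

series, truth = build_phantom(preset_spec("tiny"))
maps = run_parallel(series, RunConfig(svd_rel_threshold=0.0, mask_frac=0.01,
                                      workers=2))
# maps.cbf, maps.cbv, maps.mtt, maps.ttp, maps.ta: (z, y, x) arrays
```

`run_serial` and `run_parallel` are guaranteed to produce bit-identical
outputs for any worker count and chunking — scheduling never touches the
per-voxel floating-point sequence.

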