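# Methods

## Problem and model

The package learns a supervised mapping from a low-resolution,
3-component velocity volume **u** ∈ ℝ^(H×W×D×3) to its high-resolution
counterpart **U** ∈ ℝ^(sH×sW×sD×3), s ∈ {2, 3, 4}.  Temporal frames of a
cardiac cycle are treated as independent samples; only spatial resolution
is changed.  The three components are super-resolved jointly because they
encode one underlying flow direction field.

Architecture (channels-first, (3, H, W, D) in, (3, sH, sW, sD) out):

* head: 3×3×3 convolution, 3 → C channels;
* body: N residual groups of M residual blocks.  Each block is a 1×1×1
  widening convolution C → pC, ReLU, 3×3×3 projection pC → C, a
  squeeze-and-excitation (SE) gate, and an identity skip.  Each group adds
  a skip around its blocks, and one global skip spans the whole body.
  The SE gate pools each channel to its global mean, passes the C-vector
  through a C → C/r → C bottleneck (ReLU, then sigmoid) and rescales the
  channels by the resulting (0, 1) gains;
* tails: the body output and the raw 3-channel input each pass through a
  3×3×3 "refining" convolution to s³C channels followed by a 3D voxel
  shuffle to (C, sH, sW, sD); the two branches are summed and a final
  3×3×3 convolution produces the 3 output components.

All convolutions use weight normalization (w = g·v/‖v‖ per output
channel), zero-initialized biases, and He-scaled directions.  The
`wdsr3d` variant removes the SE gates and the group/global skips (a flat
chain of wide-activation blocks) and is the learned baseline.

Where the block sequence left choices open we fixed: ReLU as the
nonlinearity, kernel sizes 1–3–(1×1 SE dense layers) inside the block,
3×3×3 for head/tails/final, and branch summation *before* the final
convolution.  Defaults C = 32, N = 4, M = 2, p = 32, r = 8; a tiny preset
(C = 8, N = M = 1, p = 4, r = 4; 27 872 parameters at s = 2) is used for
CPU-scale training and all tests.

The implementation runs on a small reverse-mode autodiff core over NumPy
(`srflow._nn`): broadcast arithmetic, same-padding 3D convolution via
strided sliding windows, dense layers, voxel shuffle, and a
differentiable one-axis finite-difference operator.  Gradients are exact
(verified against central finite differences at 1e-4 relative in the
tests); float64 throughout.

## Loss functions

For reference u and prediction v per voxel:

* ℓ1: J_ℓ1 = (1/n) Σ ‖v_i − u_i‖₁ (sum over the 3 components, mean over
  voxels only; any component-averaging constant would be absorbed by the
  λ weights).
* mutually projected ℓ1: J1(v;u) = |‖u‖ − (u·v)/‖u‖| vanishes on the
  plane {v : u·v = ‖u‖²}; J2(v;u) = |‖v‖ − (u·v)/‖v‖| vanishes on the
  sphere ‖v − u/2‖ = ‖u‖/2.  J_mp = (1/n) Σ (αJ1 + βJ2) with
  α = β = 0.5.  Both terms are computed in dot-product form; denominators
  are floored at eps = 1e-8 (normalized-velocity units) so u = 0 or
  v = 0 voxels stay finite and subdifferentiable.  The two zero sets are
  tangent at v = u, so the loss surface is quadratically flat along the
  tangent plane near the minimum — relevant when locating the minimum by
  grid search.
* combined: J_opt = λ_ℓ1 J_ℓ1 + λ_mp J_mp (defaults 1 and 1), optionally
  + λ_div · (1/n) Σ |∇·v_i|², the divergence computed with
  central differences (one-sided at boundaries) on the voxel spacing.
  Presets: `l1`, `mp_l1`, `opt`, `l1_div`, `opt_div`.

Training losses are computed over all patch voxels (no masking); masked
evaluation is a metrics-level concern.

## Degradation model (training-pair synthesis)

Given a high-resolution field with velocity scale v_max:

1. each component becomes the phase of a complex signal,
   φ_c = v_c / venc with venc = v_max/π, so φ spans ±π exactly at
   ±v_max with no wrapping (a 1e-6 relative headroom guards the ±π
   ambiguity); the magnitude is a dummy — the vessel mask or all-ones;
2. per component: FFT, fftshift, keep the central (H/s, W/s, D/s) block
   (the DC bin n//2 always falls in the kept half; the even-length
   Nyquist bin is dropped deterministically by the floor-centred crop);
3. complex Gaussian noise is added to the kept samples with per-part
   standard deviation noise_sd · mean|K_cropped| / √2 (noise_sd default
   0.05); the noise is added after cropping, i.e. only to retained
   samples — adding it before cropping would differ only in the discarded
   bins;
4. inverse FFT divided by s³, so constant volumes keep their value and
   the velocity scale is unchanged; phases are decoded as
   v_c = venc·arg(signal).

Grid convention: the inverse DFT of the centre-cropped spectrum evaluates
the band-limited field at HR index s·j for LR index j — **corner
alignment**.  The cubic-spline baseline and patch extraction use the same
mapping (HR window at s × the LR origin).  Spatial dimensions must be
divisible by s; there is no implicit padding.

Velocities are normalized to [−1, 1] by a single v_max per dataset (the
maximum speed over the training references); the fitted estimator stores
it (`v_max_`) and reapplies it at inference.

## Metrics

PVNR = 20 log10(1/RMS_vel) dB with RMS_vel = √(mean ‖u−v‖²)/max‖u‖ (the
root of the mean is taken first, then normalized by the peak reference
speed); RMS_speed analogously on ‖u‖−‖v‖; Edir = mean(1 − cosθ) over
voxels with ‖u‖‖v‖ above 1e-12·(peak speed)², where the metric is
defined; RMS_div = √(mean (∇·v)²) with second-order central differences
(one-sided at boundaries) on the stored spacing.  Spacing units are used
as stored: spacing in metres with velocity in m/s gives RMS_div in 1/s;
unit spacing gives velocity units per voxel.  Voxel count N and peak
speed are taken over the evaluation mask when one is supplied.  Exact
matches report a capped PVNR of 140 dB.

## Training loop

ADAM (β = 0.9/0.999), learning rate 1e-3 with a staircase decay of 0.9
after every 10 epochs, batch size 4, default 200 epochs, best checkpoint
chosen by validation PVNR (earliest epoch on ties) computed on whole
degraded volumes, not patches.  An "epoch" is `patches_per_epoch`
(default 500) randomly positioned patches, drawn on the fly from the
training volumes; LR patch shapes default to 24×24×12, 16×16×8 and
12×12×6 for s = 2, 3, 4 (clipped to the volume).  Every random draw —
initialization, patch positions, k-space noise — derives from one seed,
so (seed → history) is a pure function on one machine.  Fine-tuning
reuses a fitted model's weights with fresh optimizer state.

Tiled inference trims half of the tile overlap from interior tile faces
(where zero padding corrupts the convolutions) before averaging the
remaining cores.  Note the SE gates are functions of the global channel
means, so tiled and whole-volume inference coincide exactly only for the
`wdsr3d` variant; for the SE variant the residual difference is governed
by how much the pooled statistics vary between tiles.

## Synthetic data

The generators emulate what matters to this pipeline about vascular
velocity fields — spatial smoothness, incompressibility, a vessel mask,
pulsatile amplitude modulation over the cardiac cycle:

* `abc_flow`: the Arnold–Beltrami–Childress flow on a periodic grid; each
  component is independent of its own coordinate, so even its
  finite-difference divergence is exactly zero;
* `poiseuille_tube`: parabolic axial profile inside a circular mask,
  centred on an integer voxel so the r = 0 centerline is sampled;
* `solenoidal_random_field`: the spectral curl of a Gaussian-smoothed
  random vector potential (correlation length = `smoothness_sigma`
  voxels, default 2); its *spectral* divergence is identically zero while
  its central-difference divergence is a small discretization residual
  that shrinks as the field gets smoother.  Fields are scaled to a peak
  speed of `v_scale` (default 1 m/s, commensurate with clinical venc
  ranges of 0.8–1.5 m/s).

What they do not emulate: vessel-geometry-specific flow structure,
non-Gaussian magnitude noise, phase aliasing, eddy-current offsets,
scan-rescan variability.  Tests passing on these fields therefore
validate the pipeline's mechanics and the learning signal, not clinical
performance on in vivo data.

## Desk-scale experiment sizes

The bundled end-to-end experiment (tests and `scripts/acceptance.py`)
uses 40 solenoidal 32³ volumes (30 train / 10 held out), 2× degradation
with noise_sd 0.05, the tiny preset, and 15 epochs of 200 patches of
8×8×8 LR voxels — sizes chosen so the full run completes in about a
minute on one CPU core while the learned model still clearly outperforms
cubic-spline upsampling on held-out volumes.

## Known limitations

* No temporal super-resolution; frames are independent samples.
* Component axes follow voxel-index order; NIfTI affines contribute only
  voxel spacing, and no reorientation to scanner/physical axes is applied.
* Divergence accuracy is bounded by the finite-difference scheme.
* The NumPy training core is single-device, float64, and sized for
  desk-scale models; the full-size defaults (C = 32, p = 32) train only
  with patience.
* Phase unwrapping, DICOM ingestion, and adversarial objectives are out
  of scope.
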