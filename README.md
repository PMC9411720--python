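# srflow

Learned super-resolution of 4D-flow MRI velocity fields.

4D-flow (phase-contrast) MRI measures time-resolved 3-component blood-flow
velocity maps, but clinically feasible scans trade spatial resolution against
noise and acquisition time, which degrades downstream hemodynamic
quantities — wall-derived gradients, streamlines, divergence.  `srflow`
post-processes reconstructed velocity volumes: a residual 3D convolutional
network learns the mapping from a low-resolution velocity field
**u** ∈ ℝ^(H×W×D×3) to its high-resolution counterpart
**U** ∈ ℝ^(sH×sW×sD×3) for upscaling factors s ∈ {2, 3, 4}, treating the
three velocity components jointly.  It targets researchers working with
phase-contrast velocity data who want a stronger-than-spline upsampler with
an end-to-end testable training pipeline.

## What is inside

* **Network** — wide-activation residual blocks (1×1×1 channel widening by
  p, ReLU, 3×3×3 projection) with squeeze-and-excitation channel gates,
  arranged in N residual groups of M blocks with hierarchical skips; a
  coarse branch upsamples the raw input by 3D voxel shuffling and the deep
  branch adds the fine detail.  A plain wide-activation variant without SE
  gates (`variant="wdsr3d"`) serves as the learned baseline.  The layers run
  on a compact NumPy reverse-mode autodiff core (`srflow._nn`), so training
  and inference need no GPU framework.
* **Loss** — the mutually projected ℓ1 loss for 3-vectors.  With reference
  u and prediction v, J1 = |‖u‖ − ‖v‖cosθ| vanishes on the plane through u
  orthogonal to u and J2 = |‖v‖ − ‖u‖cosθ| on the sphere of radius ‖u‖/2
  centred at u/2; their convex combination αJ1 + βJ2 (α + β = 1) has its
  unique joint zero at v = u and penalizes errors direction-dependently.
  The default objective is J_opt = λ_ℓ1 J_ℓ1 + λ_mp J_mp-ℓ1 (λ = 1, 1),
  optionally plus a mean-squared-divergence regularizer.
* **Degradation model** — training pairs are simulated from high-resolution
  fields by phase-encoding each velocity component at venc = v_max/π,
  truncating the central block of k-space by the scale factor, adding
  seeded complex Gaussian noise, and inverting back to velocities.
* **Metrics** — PVNR = 20·log10(1/NRMSE) dB, normalized RMS speed error,
  direction error Edir ∈ [0, 2] (mean 1 − cosine similarity), and RMS
  divergence, all mask-aware.
* **Synthetic flows** — analytic divergence-free generators
  (Arnold–Beltrami–Childress flow, Poiseuille tube flow, smoothed random
  solenoidal fields) with pulsatile temporal modulation, so the whole
  pipeline is testable without acquired data.
* **Baseline** — tensor-product cubic B-spline upsampling on the same grid
  convention.

## Worked example

```python
import numpy as np
import srflow as sf

# 20 synthetic divergence-free volumes, degraded 2x with 5% k-space noise
fields = [sf.solenoidal_random_field(sf.FlowRecipe(shape=(32, 32, 32), seed=i))
          for i in range(20)]
series = [sf.pulsatile_series(f, 1, "constant") for f in fields]
dcfg = sf.DegradationConfig(scale=2, v_max=1.0, noise_sd=0.05, seed=0)
X, y = sf.series_to_arrays(series, dcfg)

est = sf.SRFlowRegressor(scale=2, loss="opt", epochs=10, patches_per_epoch=200,
                         patch_shape=(8, 8, 8), random_state=0,
                         base_channels=8, n_groups=1, blocks_per_group=1,
                         expansion=4, se_reduction=4)
est.fit(X[:15], y[:15], X[15:], y[15:])

spline = sf.CubicSplineUpsampler(scale=2).fit()
for name, pred in [("srflow", est.predict(X[15:])),
                   ("spline", spline.predict(X[15:]))]:
    print(name, round(float(np.mean([sf.pvnr(p, r)
                                     for p, r in zip(pred, y[15:])])), 2), "dB")
```

Output from this exact script:

```
srflow 22.16 dB
spline 21.32 dB
```

i.e. after ten epochs the tiny network preset already reconstructs the
held-out volumes with ~0.8 dB higher peak-velocity-to-noise ratio than
cubic-spline upsampling of the same degraded inputs.  The same workflow is
available from the shell:

```bash
srflow simulate field.nii.gz --kind solenoidal_random --shape 32,32,32
srflow degrade field.nii.gz low.nii.gz --scale 2 --noise-sd 0.05
srflow train --config train.yaml --checkpoint model.npz
srflow infer low.nii.gz sr.nii.gz --checkpoint model.npz
srflow evaluate field.nii.gz sr.nii.gz
```

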