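"""Analytic, divergence-free synthetic velocity fields.

These generators emulate the qualitative features of vascular 4D-flow
data — spatially smooth, incompressible, masked velocity fields with
pulsatile temporal modulation — so the degradation model, losses, metrics
and training loop can all be exercised end-to-end without acquired data.

Three field families:

* ``abc_flow`` — the Arnold–Beltrami–Childress flow on a periodic grid,
  divergence-free in closed form (each component is independent of its
  own coordinate, so even finite differences vanish identically).
* ``poiseuille_tube`` — steady laminar tube flow with a parabolic axial
  profile and an inside-tube mask.
* ``solenoidal_random_field`` — the curl of a smoothed random vector
  potential, taken spectrally on the periodic grid so the spectral
  divergence is exactly zero; this is the workhorse for training-scale
  experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume import FlowSeries, VelocityField

__all__ = [
    "FlowRecipe",
    "abc_flow",
    "poiseuille_tube",
    "solenoidal_random_field",
    "make_field",
    "pulsatile_series",
]


@dataclass
class FlowRecipe:
    """Parameters of one synthetic flow field."""

    kind: Literal["abc", "poiseuille", "solenoidal_random"] = "solenoidal_random"
    shape: tuple = (32, 32, 32)
    spacing: tuple = (1.0, 1.0, 1.0)
    # ABC amplitudes
    A: float = 1.0
    B: float = 1.0
    C_coef: float = 1.0
    # Poiseuille
    radius: float = 0.35  # fraction of the min cross-section half-extent
    v_peak: float = 1.0
    axis: int = 2
    # solenoidal random
    smoothness_sigma: float = 2.0  # voxels; correlation length of the potential
    v_scale: float = 1.0  # target max speed, m/s
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n < 8 for n in self.shape):
            raise ValueError("shape must be 3 axes of at least 8 voxels each")
        if not np.all(np.isfinite([self.A, self.B, self.C_coef, self.v_peak,
                                   self.v_scale])):
            raise ValueError("amplitudes must be finite")


def abc_flow(recipe: FlowRecipe) -> VelocityField:
    """Arnold–Beltrami–Childress flow sampled on a periodic grid.

    u1 = A sin(z) + C cos(y); u2 = B sin(x) + A cos(z);
    u3 = C sin(y) + B cos(x), with each axis spanning [0, 2*pi).
    """
    H, W, D = recipe.shape
    x = 2 * np.pi * np.arange(H) / H
    y = 2 * np.pi * np.arange(W) / W
    z = 2 * np.pi * np.arange(D) / D
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    A, B, C = recipe.A, recipe.B, recipe.C_coef
    data = np.stack(
        [
            A * np.sin(Z) + C * np.cos(Y),
            B * np.sin(X) + A * np.cos(Z),
            C * np.sin(Y) + B * np.cos(X),
        ],
        axis=-1,
    )
    mask = np.ones(recipe.shape, dtype=np.uint8)
    v_max = float(np.max(np.sqrt(np.sum(data**2, axis=-1))))
    return VelocityField(data=data, spacing=recipe.spacing, mask=mask, v_max=v_max)


def poiseuille_tube(recipe: FlowRecipe) -> VelocityField:
    """Parabolic tube flow: w(r) = v_peak (1 - r^2/R^2) inside radius R."""
    if recipe.axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    H, W, D = recipe.shape
    cross_axes = [a for a in range(3) if a != recipe.axis]
    extents = [recipe.shape[a] for a in cross_axes]
    R = recipe.radius * min(extents) / 2.0
    if R >= min(extents) / 2.0:
        raise ValueError("tube radius exceeds the domain cross-section")
    # centre on an integer voxel so the centerline (r = 0) is sampled
    coords = [np.arange(n) - n // 2 for n in recipe.shape]
    grids = np.meshgrid(*coords, indexing="ij")
    r2 = grids[cross_axes[0]] ** 2 + grids[cross_axes[1]] ** 2
    inside = r2 <= R**2
    axial = np.where(inside, recipe.v_peak * (1.0 - r2 / R**2), 0.0)
    data = np.zeros(recipe.shape + (3,))
    data[..., recipe.axis] = axial
    return VelocityField(
        data=data,
        spacing=recipe.spacing,
        mask=inside.astype(np.uint8),
        v_max=float(recipe.v_peak),
    )


def solenoidal_random_field(recipe: FlowRecipe) -> VelocityField:
    """Curl of a smoothed seeded random vector potential, taken spectrally.

    The potential is white Gaussian noise low-pass filtered with a Gaussian
    of ``smoothness_sigma`` voxels; its curl is evaluated with spectral
    derivatives on the periodic grid, so the spectral divergence of the
    result is identically zero.  The field is rescaled so the maximum
    speed equals ``v_scale``.
    """
    rng = np.random.default_rng(recipe.seed)
    shape = recipe.shape
    potential = rng.standard_normal(size=(3,) + shape)
    potential = np.stack(
        [ndimage.gaussian_filter(p, recipe.smoothness_sigma, mode="wrap")
         for p in potential]
    )

    freqs = [2j * np.pi * np.fft.fftfreq(n) for n in shape]
    KX = freqs[0][:, None, None]
    KY = freqs[1][None, :, None]
    KZ = freqs[2][None, None, :]
    Ahat = [np.fft.fftn(potential[i]) for i in range(3)]
    # curl in Fourier space: (dAz/dy - dAy/dz, dAx/dz - dAz/dx, dAy/dx - dAx/dy)
    cx = np.fft.ifftn(KY * Ahat[2] - KZ * Ahat[1]).real
    cy = np.fft.ifftn(KZ * Ahat[0] - KX * Ahat[2]).real
    cz = np.fft.ifftn(KX * Ahat[1] - KY * Ahat[0]).real
    data = np.stack([cx, cy, cz], axis=-1)

    speed = np.sqrt(np.sum(data**2, axis=-1))
    peak = speed.max()
    if peak > 0:
        data *= recipe.v_scale / peak
    mask = np.ones(shape, dtype=np.uint8)
    return VelocityField(
        data=data, spacing=recipe.spacing, mask=mask, v_max=float(recipe.v_scale)
    )


_GENERATORS = {
    "abc": abc_flow,
    "poiseuille": poiseuille_tube,
    "solenoidal_random": solenoidal_random_field,
}


def make_field(recipe: FlowRecipe) -> VelocityField:
    """Dispatch on ``recipe.kind``."""
    return _GENERATORS[recipe.kind](recipe)


def pulsatile_series(
    base: VelocityField,
    n_frames: int,
    waveform: Literal["constant", "half_sine"] = "half_sine",
    period: Optional[float] = None,
) -> FlowSeries:
    """Scale one spatial field by a cardiac-like waveform over n_frames.

    ``constant`` repeats the field; ``half_sine`` modulates by
    sin(pi (t + 1) / (n + 1)) for t = 0..n-1, rising to exactly 1.0 at the
    peak frame for odd n.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    frames = []
    for t in range(n_frames):
        if waveform == "constant":
            scale = 1.0
        elif waveform == "half_sine":
            scale = float(np.sin(np.pi * (t + 1) / (n_frames + 1)))
        else:
            raise ValueError(f"unknown waveform {waveform!r}")
        frames.append(base.replace(data=base.data * scale, frame_index=t))
    return FlowSeries(frames=frames, period=period)
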