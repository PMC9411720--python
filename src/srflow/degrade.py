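"""k-space degradation model: velocity -> phase -> truncation -> noise -> velocity.

Training pairs are produced by simulating how a lower-resolution
phase-contrast acquisition would have seen the reference field:

1. each velocity component becomes the phase of a complex signal,
   phi = v / venc with venc = v_max / pi (so phase spans +-pi with no
   wrapping); a dummy magnitude (the vessel mask, or ones) carries the
   signal;
2. the complex volume is transformed to k-space and the central
   (H/s, W/s, D/s) block of spatial frequencies is kept;
3. seeded complex Gaussian noise is added to the kept samples, with
   standard deviation expressed relative to the mean magnitude of the
   cropped spectrum;
4. the inverse transform (normalized so constant volumes keep their
   value) and phase extraction give the low-resolution velocities.

Grid convention: the inverse DFT of the centre-cropped spectrum evaluates
the band-limited field at high-resolution index s*j for low-resolution
index j, i.e. LR voxel j sits on HR voxel s*j (corner alignment).  The
spline baseline uses the same mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .volume import FlowSeries, VelocityField

__all__ = [
    "DegradationConfig",
    "ComplexVolumeSet",
    "PatchPair",
    "velocity_to_complex",
    "kspace_downsample",
    "complex_to_velocity",
    "degrade_field",
    "degrade_series",
    "extract_patch_pair",
]

#: tolerated overshoot of |v| beyond v_max before phase wrapping is declared
WRAP_HEADROOM = 1e-6


@dataclass
class DegradationConfig:
    """Parameters of the simulated low-resolution acquisition.

    scale=1 with noise_sd=0 is the identity path used for testing.
    noise_sd is the complex-noise standard deviation as a fraction of the
    mean magnitude of the cropped k-space region.
    """

    scale: int = 2
    v_max: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0
    magnitude_source: Literal["mask", "ones"] = "ones"

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")

    @property
    def venc(self) -> float:
        """Velocity-encoding value: v_max / pi, so phase spans +-pi."""
        return self.v_max / np.pi


@dataclass
class ComplexVolumeSet:
    """Three complex volumes (one per velocity component), image or k-space."""

    volumes: np.ndarray  # (3, H, W, D) complex
    domain: Literal["image", "kspace"]
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        if self.volumes.ndim != 4 or self.volumes.shape[0] != 3:
            raise ValueError(
                f"expected (3, H, W, D) complex volumes, got {self.volumes.shape}"
            )
        if not np.all(np.isfinite(self.volumes)):
            raise ValueError("complex volumes contain non-finite values")


@dataclass
class PatchPair:
    """An aligned low-/high-resolution training sample."""

    lr_patch: np.ndarray  # (h, w, d, 3)
    hr_patch: np.ndarray  # (s h, s w, s d, 3)
    lr_origin: tuple

    def __post_init__(self) -> None:
        s = self.hr_patch.shape[0] // self.lr_patch.shape[0]
        if tuple(np.asarray(self.lr_patch.shape[:3]) * s) != self.hr_patch.shape[:3]:
            raise ValueError("hr patch shape must be s x lr patch shape")


def velocity_to_complex(
    field: VelocityField,
    cfg: DegradationConfig,
    magnitude: Optional[np.ndarray] = None,
) -> ComplexVolumeSet:
    """Encode each velocity component as the phase of a complex signal.

    phi_c = v_c / venc; with venc = v_max/pi, |phi| <= pi exactly at
    |v| = v_max.  ``magnitude`` defaults to the vessel mask or to ones,
    per ``cfg.magnitude_source``.
    """
    vmax_obs = np.abs(field.data).max()
    if vmax_obs > cfg.v_max * (1.0 + WRAP_HEADROOM):
        raise ValueError(
            f"velocity magnitude {vmax_obs:.6g} exceeds v_max {cfg.v_max:.6g}: "
            "phase would wrap"
        )
    if magnitude is None:
        if cfg.magnitude_source == "mask" and field.mask is not None:
            magnitude = field.mask.astype(np.float64)
        else:
            magnitude = np.ones(field.spatial_shape)
    phase = field.data / cfg.venc  # (H, W, D, 3)
    vols = magnitude[None] * np.exp(1j * np.moveaxis(phase, -1, 0))
    return ComplexVolumeSet(volumes=vols, domain="image", spacing=field.spacing)


def _center_crop_slices(n: int, m: int) -> slice:
    """Slice keeping the m central (shifted) frequency bins out of n."""
    start = n // 2 - m // 2
    return slice(start, start + m)


def kspace_downsample(
    vols: ComplexVolumeSet, cfg: DegradationConfig
) -> ComplexVolumeSet:
    """Truncate each volume's spectrum to its central block and add noise.

    Forward FFT per component; fftshift; keep the central (H/s, W/s, D/s)
    block around DC (the even-length Nyquist bin falls in the kept half
    deterministically via the floor-centred crop); add seeded complex
    Gaussian noise to the kept samples; inverse FFT divided by s^3 so a
    constant volume keeps its value.  Returns an image-domain set at the
    low-resolution shape with spacing multiplied by s.
    """
    if vols.domain != "image":
        raise ValueError("kspace_downsample expects an image-domain set")
    s = cfg.scale
    shape = vols.volumes.shape[1:]
    if any(n % s for n in shape):
        raise ValueError(f"spatial shape {shape} not divisible by scale {s}")
    lr_shape = tuple(n // s for n in shape)
    slices = tuple(_center_crop_slices(n, m) for n, m in zip(shape, lr_shape))

    rng = np.random.default_rng(cfg.seed)
    out = np.empty((3,) + lr_shape, dtype=np.complex128)
    for c in range(3):
        K = np.fft.fftshift(np.fft.fftn(vols.volumes[c]))
        Kc = K[slices].copy()
        if cfg.noise_sd > 0:
            sd = cfg.noise_sd * np.mean(np.abs(Kc)) / np.sqrt(2.0)
            Kc += sd * (
                rng.standard_normal(lr_shape) + 1j * rng.standard_normal(lr_shape)
            )
        out[c] = np.fft.ifftn(np.fft.ifftshift(Kc)) / s**3
    return ComplexVolumeSet(
        volumes=out, domain="image", spacing=vols.spacing * s
    )


def complex_to_velocity(
    vols: ComplexVolumeSet, cfg: DegradationConfig
) -> VelocityField:
    """Recover velocities from signal phase: v_c = venc * arg(signal_c)."""
    if vols.domain != "image":
        raise ValueError("complex_to_velocity expects an image-domain set")
    phase = np.angle(vols.volumes)  # (3, H, W, D)
    data = cfg.venc * np.moveaxis(phase, 0, -1)
    return VelocityField(data=data, spacing=vols.spacing, v_max=cfg.v_max)


def degrade_field(
    field: VelocityField, cfg: DegradationConfig, seed: Optional[int] = None
) -> VelocityField:
    """Full degradation of one frame (optionally overriding the noise seed)."""
    use = cfg if seed is None else DegradationConfig(
        scale=cfg.scale, v_max=cfg.v_max, noise_sd=cfg.noise_sd,
        seed=seed, magnitude_source=cfg.magnitude_source,
    )
    sig = velocity_to_complex(field, use)
    lo = kspace_downsample(sig, use)
    out = complex_to_velocity(lo, use)
    return out.replace(frame_index=field.frame_index)


def degrade_series(series: FlowSeries, cfg: DegradationConfig) -> FlowSeries:
    """Degrade every frame; per-frame noise seeds advance deterministically."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(series))
    frames = [
        degrade_field(f, cfg, seed=int(seeds[i] % (2**31)))
        for i, f in enumerate(series)
    ]
    return FlowSeries(frames=frames, period=series.period)


def extract_patch_pair(
    lr: VelocityField,
    hr: VelocityField,
    s: int,
    lr_shape: Sequence[int],
    rng: np.random.Generator,
) -> PatchPair:
    """Cut an aligned random LR/HR patch pair.

    The HR window starts at s times the LR origin, matching the corner
    alignment of the k-space decimation.
    """
    lr_shape = tuple(int(n) for n in lr_shape)
    vol_shape = lr.spatial_shape
    if any(p > v for p, v in zip(lr_shape, vol_shape)):
        raise ValueError(f"patch {lr_shape} larger than volume {vol_shape}")
    if tuple(np.asarray(vol_shape) * s) != hr.spatial_shape:
        raise ValueError("hr volume shape must be s x lr volume shape")
    origin = tuple(
        int(rng.integers(0, v - p + 1)) for p, v in zip(lr_shape, vol_shape)
    )
    lr_sl = tuple(slice(o, o + p) for o, p in zip(origin, lr_shape))
    hr_sl = tuple(slice(s * o, s * (o + p)) for o, p in zip(origin, lr_shape))
    return PatchPair(
        lr_patch=lr.data[lr_sl], hr_patch=hr.data[hr_sl], lr_origin=origin
    )
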