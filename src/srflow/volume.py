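"""Domain containers and I/O for 3-component velocity volumes.

A velocity volume is a rank-4 grid ``(H, W, D, 3)`` holding one temporal
frame of a phase-contrast MRI velocity map (m/s), together with voxel
spacing, an optional binary vessel mask, and the velocity scale ``v_max``
used for normalization.

Component convention: component ``i`` is the velocity along voxel-index
axis ``i``.  NIfTI affines are read only for voxel spacing; no reorientation
to scanner/physical axes is applied.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VelocityField",
    "FlowSeries",
    "MetricsReport",
    "read_velocity_volume",
    "write_velocity_volume",
    "normalize_velocity",
]

Layout = Literal["four_d", "three_scalars"]


@dataclass
class VelocityField:
    """One temporal frame of a 3-component velocity grid.

    Parameters
    ----------
    data : ndarray, shape (H, W, D, 3)
        Velocity components in m/s; component i points along voxel axis i.
    spacing : sequence of 3 floats
        Voxel edge length per axis (mm by convention; divergence metrics
        use whatever unit is stored here).
    mask : ndarray of shape (H, W, D) or None
        Nonzero marks voxels inside the vessel lumen.
    v_max : float or None
        Velocity scale (m/s) used for [-1, 1] normalization; one scalar
        per dataset, not per frame.
    frame_index : int
        Position of this frame in the cardiac cycle.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    mask: Optional[np.ndarray] = None
    v_max: Optional[float] = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"velocity data must have shape (H, W, D, 3), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("velocity data contains non-finite values")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"spatial shape {self.data.shape[:3]}"
                )
        if self.v_max is not None and self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def speed(self) -> np.ndarray:
        """Voxelwise speed ``||v||_2``, shape (H, W, D)."""
        return np.sqrt(np.sum(self.data**2, axis=-1))

    def replace(self, **kwargs) -> "VelocityField":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass
class FlowSeries:
    """Ordered cardiac frames sharing grid, spacing, and mask."""

    frames: list
    period: Optional[float] = None  # cardiac cycle length, ms

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a flow series needs at least one frame")
        shape0 = self.frames[0].spatial_shape
        for f in self.frames:
            if f.spatial_shape != shape0:
                raise ValueError("all frames must share the same spatial shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class MetricsReport:
    """Quality metrics for one prediction/reference volume pair.

    pvnr is in dB; rms_speed is normalized by the reference peak speed;
    edir lies in [0, 2] (0 = parallel, 2 = antiparallel); rms_div is in
    velocity units per spacing unit.
    """

    pvnr: float
    rms_speed: float
    edir: float
    rms_div: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.edir <= 2.0 + 1e-12):
            raise ValueError(f"edir must lie in [0, 2], got {self.edir}")
        if self.rms_speed < 0 or self.rms_div < 0:
            raise ValueError("rms metrics must be non-negative")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COMPONENT_SUFFIXES = ("_vx", "_vy", "_vz")
_MASK_SUFFIX = "_mask"


def _split_nifti_path(path: str) -> tuple:
    base = str(path)
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            return base[: -len(ext)], ext
    return base, ".nii.gz"


def _spacing_from_header(img) -> np.ndarray:
    zooms = img.header.get_zooms()[:3]
    return np.asarray(zooms, dtype=np.float64)


def _affine_from_spacing(spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_velocity_volume(path: str, layout: Layout = "four_d") -> VelocityField:
    """Read a velocity volume from NIfTI or an ``.npz`` archive.

    ``four_d`` expects one 4D NIfTI with the 3 components in the 4th axis
    (or an .npz with keys ``velocity``/``mask``/``spacing``); ``three_scalars``
    expects sibling files ``<stem>_vx/_vy/_vz.nii[.gz]``.  A mask sidecar
    ``<stem>_mask`` is picked up when present.
    """
    spath = str(path)
    if spath.endswith(".npz"):
        with np.load(spath) as z:
            data = z["velocity"]
            mask = z["mask"] if "mask" in z.files else None
            spacing = z["spacing"] if "spacing" in z.files else np.ones(3)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError(f"expected (H, W, D, 3) velocity array, got {data.shape}")
        return VelocityField(data=data, spacing=spacing, mask=mask)

    stem, ext = _split_nifti_path(spath)
    if layout == "four_d":
        img = nib.load(spath)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError(
                f"expected a 4D NIfTI with 3 components in the last axis, "
                f"got shape {data.shape}"
            )
        spacing = _spacing_from_header(img)
    elif layout == "three_scalars":
        comps = []
        spacing = None
        for suf in _COMPONENT_SUFFIXES:
            cpath = stem + suf + ext
            if not os.path.exists(cpath):
                raise FileNotFoundError(cpath)
            img = nib.load(cpath)
            comps.append(np.asanyarray(img.dataobj))
            spacing = _spacing_from_header(img)
        shapes = {c.shape for c in comps}
        if len(shapes) != 1 or comps[0].ndim != 3:
            raise ValueError(f"component volumes disagree in shape: {shapes}")
        data = np.stack(comps, axis=-1)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    mask = None
    mpath = stem + _MASK_SUFFIX + ext
    if os.path.exists(mpath):
        mask = np.asanyarray(nib.load(mpath).dataobj).astype(np.uint8)
    return VelocityField(data=data, spacing=spacing, mask=mask)


def write_velocity_volume(
    field: VelocityField, path: str, layout: Layout = "four_d"
) -> None:
    """Write a velocity volume as NIfTI (4D or three scalars) or ``.npz``.

    The mask, when present, is written as a uint8 sidecar ``<stem>_mask``.
    """
    spath = str(path)
    if spath.endswith(".npz"):
        payload = {"velocity": field.data, "spacing": field.spacing}
        if field.mask is not None:
            payload["mask"] = field.mask.astype(np.uint8)
        np.savez_compressed(spath, **payload)
        return

    aff = _affine_from_spacing(field.spacing)
    stem, ext = _split_nifti_path(spath)
    if layout == "four_d":
        nib.save(nib.Nifti1Image(field.data, aff), stem + ext)
    elif layout == "three_scalars":
        for i, suf in enumerate(_COMPONENT_SUFFIXES):
            nib.save(nib.Nifti1Image(field.data[..., i], aff), stem + suf + ext)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if field.mask is not None:
        nib.save(
            nib.Nifti1Image(field.mask.astype(np.uint8), aff),
            stem + _MASK_SUFFIX + ext,
        )


def normalize_velocity(
    field: VelocityField, v_max: float, inverse: bool = False
) -> VelocityField:
    """Scale velocities into [-1, 1] by v_max (forward) or back (inverse)."""
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    data = field.data * v_max if inverse else field.data / v_max
    return field.replace(data=data, v_max=v_max)
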