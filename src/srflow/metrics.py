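"""Flow-field quality metrics: PVNR, RMS_speed, Edir, RMS_div.

All voxelwise metrics accept an optional evaluation mask (the region of
interest); the voxel count N and the reference peak speed used for
normalization are taken over the mask when one is given.  ``pred`` and
``ref`` may be VelocityField objects or (H, W, D, 3) arrays.

PVNR = 20 log10(1 / RMS_vel) dB, with RMS_vel the root-mean-squared
vector error normalized by the reference peak speed.  Edir is the mean
of 1 - cos(angle between prediction and reference) over voxels where
both vectors are non-negligible; it separates direction error from the
magnitude error RMS_speed.  RMS_div is the root-mean-squared
central-difference divergence, a measure of departure from
incompressibility, in velocity units per spacing unit.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .volume import MetricsReport, VelocityField

__all__ = [
    "rms_vel",
    "pvnr",
    "rms_speed",
    "direction_error",
    "rms_divergence",
    "evaluate",
    "PVNR_CAP_DB",
]

PVNR_CAP_DB = 140.0
EDIR_EPS_REL = 1e-12  # on ||u|| ||v|| relative to peak speed squared


def _unpack(x):
    if isinstance(x, VelocityField):
        return x.data, x.spacing, x.mask
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 4 or a.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, D, 3) field, got {a.shape}")
    return a, np.ones(3), None


def _select(pred, ref, mask):
    p, _, pmask = _unpack(pred)
    u, _, umask = _unpack(ref)
    if p.shape != u.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {u.shape}")
    if mask is None:
        mask = umask if umask is not None else pmask
    if mask is not None:
        mask = np.asarray(mask) != 0
        if mask.shape != u.shape[:3]:
            raise ValueError("mask shape does not match field")
        if not mask.any():
            raise ValueError("evaluation mask is empty")
        return p[mask], u[mask]
    return p.reshape(-1, 3), u.reshape(-1, 3)


def rms_vel(pred, ref, mask: Optional[np.ndarray] = None) -> float:
    """Normalized RMS vector error: sqrt(mean ||u - v||^2) / max ||u||."""
    v, u = _select(pred, ref, mask)
    peak = np.sqrt((u**2).sum(axis=-1)).max()
    if peak == 0:
        raise ValueError("reference field is identically zero in the mask")
    return float(np.sqrt(np.mean(((u - v) ** 2).sum(axis=-1))) / peak)


def pvnr(pred, ref, mask: Optional[np.ndarray] = None,
         cap: float = PVNR_CAP_DB) -> float:
    """Peak velocity-to-noise ratio, 20 log10(1/RMS_vel) dB, capped for
    exact matches."""
    r = rms_vel(pred, ref, mask)
    if r == 0:
        return float(cap)
    return float(min(20.0 * np.log10(1.0 / r), cap))


def rms_speed(pred, ref, mask: Optional[np.ndarray] = None) -> float:
    """Normalized RMS speed (magnitude) error."""
    v, u = _select(pred, ref, mask)
    su = np.sqrt((u**2).sum(axis=-1))
    sv = np.sqrt((v**2).sum(axis=-1))
    peak = su.max()
    if peak == 0:
        raise ValueError("reference field is identically zero in the mask")
    return float(np.sqrt(np.mean((su - sv) ** 2)) / peak)


def direction_error(pred, ref, mask: Optional[np.ndarray] = None,
                    eps: Optional[float] = None) -> float:
    """Mean of 1 - cosine similarity over voxels where both speeds exceed
    the threshold; lies in [0, 2]."""
    v, u = _select(pred, ref, mask)
    su = np.sqrt((u**2).sum(axis=-1))
    sv = np.sqrt((v**2).sum(axis=-1))
    if eps is None:
        eps = EDIR_EPS_REL * max(su.max(), sv.max()) ** 2
    valid = su * sv > eps
    if not valid.any():
        raise ValueError("no voxels with non-negligible speed in both fields")
    cos = (u[valid] * v[valid]).sum(axis=-1) / (su[valid] * sv[valid])
    return float(np.mean(1.0 - np.clip(cos, -1.0, 1.0)))


def rms_divergence(field, mask: Optional[np.ndarray] = None) -> float:
    """Root-mean-squared central-difference divergence inside the mask.

    Second-order central differences in the interior, one-sided at the
    boundary planes, using the stored voxel spacing as-is.
    """
    data, spacing, fmask = _unpack(field)
    if min(data.shape[:3]) < 3:
        raise ValueError("divergence needs at least 3 voxels per axis")
    div = sum(np.gradient(data[..., i], spacing[i], axis=i) for i in range(3))
    if mask is None:
        mask = fmask
    if mask is not None:
        mask = np.asarray(mask) != 0
        if not mask.any():
            raise ValueError("evaluation mask is empty")
        div = div[mask]
    return float(np.sqrt(np.mean(div**2)))


def evaluate(pred, ref, mask: Optional[np.ndarray] = None) -> MetricsReport:
    """All four metrics for one prediction/reference pair."""
    v, u = _select(pred, ref, mask)
    return MetricsReport(
        pvnr=pvnr(pred, ref, mask),
        rms_speed=rms_speed(pred, ref, mask),
        edir=direction_error(pred, ref, mask),
        rms_div=rms_divergence(pred, mask),
        n_voxels=int(v.shape[0]),
    )
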