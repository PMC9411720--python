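"""Vector-field training losses.

Alongside the plain voxelwise l1 loss, this module implements the
mutually projected l1 loss, a direction-sensitive error for 3-vectors.
For reference u and prediction v it combines two projections

    J1(v; u) = | ||u|| - ||v|| cos(theta) | = | ||u|| - (u.v)/||u|| |
    J2(v; u) = | ||v|| - ||u|| cos(theta) | = | ||v|| - (u.v)/||v|| |

(theta the angle between u and v).  J1 vanishes on the plane through u
orthogonal to u; J2 vanishes on the sphere of radius ||u||/2 centred at
u/2.  The convex combination alpha*J1 + beta*J2 (alpha + beta = 1) has
its unique joint zero at v = u, and — unlike l1 — penalizes an error of
fixed size differently depending on its direction relative to u.

The combined training objective adds the plain l1 and mutually projected
terms with weights lambda_l1, lambda_mp, optionally plus a squared-
divergence regularizer that nudges predictions toward incompressibility.

All functions accept arrays whose last axis is the 3 vector components;
leading axes are flattened into the sample axis.  The *_t variants
operate on autodiff tensors and are used by the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import autograd as ag
from .volume import VelocityField

__all__ = [
    "LossConfig",
    "l1_loss",
    "projected_l1_J1",
    "projected_l1_J2",
    "mp_l1_loss",
    "combined_loss",
    "divergence_loss",
    "l2_loss",
    "LOSS_PRESETS",
]

EPS_DEFAULT = 1e-8


@dataclass
class LossConfig:
    """Weights of the combined objective.

    alpha/beta weight the two projections inside the mutually projected
    term (must sum to 1); lambda_* weight the l1, mutually projected and
    divergence terms of the total.
    """

    alpha: float = 0.5
    beta: float = 0.5
    lambda_l1: float = 1.0
    lambda_mp: float = 1.0
    lambda_div: float = 0.0
    eps: float = EPS_DEFAULT

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if min(self.lambda_l1, self.lambda_mp, self.lambda_div) < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


#: named presets matching the model labels used in reporting
LOSS_PRESETS = {
    "l1": dict(lambda_l1=1.0, lambda_mp=0.0, lambda_div=0.0),
    "mp_l1": dict(lambda_l1=0.0, lambda_mp=1.0, lambda_div=0.0),
    "opt": dict(lambda_l1=1.0, lambda_mp=1.0, lambda_div=0.0),
    "l1_div": dict(lambda_l1=1.0, lambda_mp=0.0, lambda_div=1.0),
    "opt_div": dict(lambda_l1=1.0, lambda_mp=1.0, lambda_div=1.0),
}


def _as_vectors(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.shape[-1] != 3:
        raise ValueError(f"last axis must hold 3 components, got shape {a.shape}")
    return a.reshape(-1, 3)


def _check_pair(pred, ref):
    v = _as_vectors(pred)
    u = _as_vectors(ref)
    if v.shape != u.shape:
        raise ValueError(f"shape mismatch: pred {v.shape} vs ref {u.shape}")
    if v.shape[0] < 1:
        raise ValueError("need at least one vector")
    return v, u


def l1_loss(pred, ref) -> float:
    """Mean over voxels of the componentwise l1 error ||v - u||_1."""
    v, u = _check_pair(pred, ref)
    return float(np.mean(np.sum(np.abs(v - u), axis=-1)))


def l2_loss(pred, ref) -> float:
    """Mean squared error over components (reference comparison only)."""
    v, u = _check_pair(pred, ref)
    return float(np.mean(np.sum((v - u) ** 2, axis=-1)))


def projected_l1_J1(v, u, eps: float = EPS_DEFAULT) -> float:
    """| ||u|| - (u.v)/||u|| | — zero on the plane {v : u.v = ||u||^2}."""
    v = np.asarray(v, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    nu = np.linalg.norm(u)
    return float(abs(nu - np.dot(u, v) / max(nu, eps)))


def projected_l1_J2(v, u, eps: float = EPS_DEFAULT) -> float:
    """| ||v|| - (u.v)/||v|| | — zero on the sphere |v - u/2| = ||u||/2."""
    v = np.asarray(v, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    nv = np.linalg.norm(v)
    return float(abs(nv - np.dot(u, v) / max(nv, eps)))


def _mp_terms(v: np.ndarray, u: np.ndarray, eps: float):
    dot = np.sum(u * v, axis=-1)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    j1 = np.abs(nu - dot / np.maximum(nu, eps))
    j2 = np.abs(nv - dot / np.maximum(nv, eps))
    return j1, j2


def mp_l1_loss(pred, ref, cfg: LossConfig = LossConfig()) -> float:
    """Mean over voxels of alpha*J1 + beta*J2."""
    v, u = _check_pair(pred, ref)
    j1, j2 = _mp_terms(v, u, cfg.eps)
    return float(np.mean(cfg.alpha * j1 + cfg.beta * j2))


def divergence_loss(field, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean squared central-difference divergence (one-sided at borders)."""
    if isinstance(field, VelocityField):
        data, spacing = field.data, field.spacing
    else:
        data = np.asarray(field, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 3 or min(data.shape[:3]) < 3:
        raise ValueError(
            f"need an (H, W, D, 3) field with at least 3 voxels per axis, "
            f"got {data.shape}"
        )
    div = sum(
        np.gradient(data[..., i], spacing[i], axis=i) for i in range(3)
    )
    return float(np.mean(div**2))


def combined_loss(
    pred, ref, cfg: LossConfig = LossConfig(), spacing=(1.0, 1.0, 1.0)
) -> float:
    """lambda_l1 * Jl1 + lambda_mp * Jmp (+ lambda_div * Jdiv on 4D input)."""
    total = 0.0
    if cfg.lambda_l1 > 0:
        total += cfg.lambda_l1 * l1_loss(pred, ref)
    if cfg.lambda_mp > 0:
        total += cfg.lambda_mp * mp_l1_loss(pred, ref, cfg)
    if cfg.lambda_div > 0:
        total += cfg.lambda_div * divergence_loss(np.asarray(pred), spacing)
    return float(total)


# ---------------------------------------------------------------------------
# autodiff variants (training path); pred is a Tensor with channels-first
# layout (B, 3, H, W, D), ref is a plain ndarray of the same shape.
# ---------------------------------------------------------------------------


def l1_loss_t(pred: "ag.Tensor", ref: np.ndarray) -> "ag.Tensor":
    n = int(np.prod(ref.shape) // 3)
    diff = pred - ag.Tensor(ref)
    return diff.abs().sum() * (1.0 / n)


def mp_l1_loss_t(
    pred: "ag.Tensor", ref: np.ndarray, cfg: LossConfig = LossConfig()
) -> "ag.Tensor":
    """Autodiff mutually projected l1 over a (B, 3, ...) batch."""
    u = np.asarray(ref, dtype=np.float64)
    n = int(np.prod(u.shape) // 3)
    dot = (pred * ag.Tensor(u)).sum(axis=1)  # (B, H, W, D)
    nu = np.linalg.norm(u, axis=1)
    nv = pred.square().sum(axis=1).sqrt_safe(cfg.eps)
    j1 = (ag.Tensor(nu) - dot * (1.0 / np.maximum(nu, cfg.eps))).abs()
    j2 = (nv - dot / nv.clip_min(cfg.eps)).abs()
    return (j1 * cfg.alpha + j2 * cfg.beta).sum() * (1.0 / n)


def divergence_loss_t(
    pred: "ag.Tensor", spacing=(1.0, 1.0, 1.0)
) -> "ag.Tensor":
    """Autodiff mean squared divergence of a (B, 3, H, W, D) batch."""
    div = None
    for i in range(3):
        d = ag.gradient_along(pred.narrow_channel(i), axis=1 + i,
                              spacing=float(spacing[i]))
        div = d if div is None else div + d
    n = int(np.prod(div.data.shape))
    return div.square().sum() * (1.0 / n)


def combined_loss_t(
    pred: "ag.Tensor",
    ref: np.ndarray,
    cfg: LossConfig = LossConfig(),
    spacing=(1.0, 1.0, 1.0),
) -> "ag.Tensor":
    total = None

    def acc(term):
        nonlocal total
        total = term if total is None else total + term

    if cfg.lambda_l1 > 0:
        acc(l1_loss_t(pred, ref) * cfg.lambda_l1)
    if cfg.lambda_mp > 0:
        acc(mp_l1_loss_t(pred, ref, cfg) * cfg.lambda_mp)
    if cfg.lambda_div > 0:
        acc(divergence_loss_t(pred, spacing) * cfg.lambda_div)
    if total is None:
        raise ValueError("all loss weights are zero")
    return total
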