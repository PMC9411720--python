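"""Super-resolution models: the SE-residual network, its wide-activation
baseline, and the classical cubic-spline upsampler.

The learned model maps a normalized low-resolution velocity patch
(3, H, W, D) to (3, sH, sW, sD).  Architecture: a head convolution lifts
the 3 components to C feature channels; N residual groups of M
wide-activation residual blocks (1x1x1 widening by p, ReLU, 3x3x3
projection, SE gate, identity skip) refine them, with a skip across each
group and a global skip across the body; deep features and the raw input
each pass through a refining convolution to s^3 C channels and a voxel
shuffle; the shuffled branches are summed and a final 3x3x3 convolution
reconstructs the 3 velocity components.  The ``wdsr3d`` variant drops
the SE gates and the group/global skips (a flat chain of blocks).

Estimators follow scikit-learn conventions: ``SRFlowRegressor`` and
``CubicSplineUpsampler`` expose fit/predict over arrays of shape
(n_volumes, H, W, D, 3) in physical velocity units.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

from ._nn.autograd import Tensor, voxel_shuffle_t
from ._nn.layers import Conv3d, Module, ResidualBlock
from ._nn.optim import Adam
from .losses import LOSS_PRESETS, LossConfig, combined_loss_t
from .volume import VelocityField

__all__ = [
    "ModelConfig",
    "SRFlowNet",
    "build_model",
    "voxel_shuffle",
    "inverse_voxel_shuffle",
    "infer",
    "cubic_spline_upsample",
    "SRFlowRegressor",
    "CubicSplineUpsampler",
    "save_checkpoint",
    "load_checkpoint",
    "TINY_PRESET",
]

#: default low-resolution training patch shape per upscaling factor
DEFAULT_PATCH_SHAPES = {1: (16, 16, 8), 2: (24, 24, 12), 3: (16, 16, 8), 4: (12, 12, 6)}

#: a desk-scale configuration for CPU training and tests
TINY_PRESET = dict(
    base_channels=8, n_groups=1, blocks_per_group=1, expansion=4, se_reduction=4
)


@dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    base_channels: int = 32  # C
    n_groups: int = 4  # N
    blocks_per_group: int = 2  # M
    expansion: int = 32  # p
    se_reduction: int = 8  # r
    scale: int = 2  # s
    weight_norm: bool = True
    variant: str = "srflow"  # or "wdsr3d"

    def __post_init__(self) -> None:
        if self.variant not in ("srflow", "wdsr3d"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if min(self.base_channels, self.n_groups, self.blocks_per_group,
               self.expansion, self.se_reduction) < 1:
            raise ValueError("all architecture sizes must be positive")
        if self.scale < 1 or self.scale > 4:
            raise ValueError("scale must be in {1, 2, 3, 4}")
        if self.variant == "srflow" and self.base_channels % self.se_reduction:
            raise ValueError("base_channels must be divisible by se_reduction")


class SRFlowNet(Module):
    """The residual super-resolution network (both variants)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        C, s, wn = cfg.base_channels, cfg.scale, cfg.weight_norm
        se = cfg.se_reduction if cfg.variant == "srflow" else None
        self.head = Conv3d(3, C, 3, rng, wn)
        self.groups: List[List[ResidualBlock]] = [
            [
                ResidualBlock(C, cfg.expansion, se, rng, wn)
                for _ in range(cfg.blocks_per_group)
            ]
            for _ in range(cfg.n_groups)
        ]
        self.deep_tail = Conv3d(C, s**3 * C, 3, rng, wn)
        self.coarse = Conv3d(3, s**3 * C, 3, rng, wn)
        self.final = Conv3d(C, 3, 3, rng, wn)

    def parameters(self) -> List[Tensor]:
        out = self.head.parameters()
        for grp in self.groups:
            for blk in grp:
                out.extend(blk.parameters())
        out.extend(self.deep_tail.parameters())
        out.extend(self.coarse.parameters())
        out.extend(self.final.parameters())
        return out

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W, D) normalized -> (B, 3, sH, sW, sD)."""
        s = self.cfg.scale
        h = self.head(x)
        if self.cfg.variant == "srflow":
            body = h
            for grp in self.groups:
                g_in = body
                for blk in grp:
                    body = blk(body)
                body = body + g_in  # group-level skip
            body = body + h  # global skip
        else:  # flat chain
            body = h
            for grp in self.groups:
                for blk in grp:
                    body = blk(body)
        deep = voxel_shuffle_t(self.deep_tail(body), s)
        coarse = voxel_shuffle_t(self.coarse(x), s)
        return self.final(deep + coarse)

    def coarse_forward(self, x: Tensor) -> Tensor:
        """The coarse branch alone (used to ablate the residual path)."""
        coarse = voxel_shuffle_t(self.coarse(x), self.cfg.scale)
        return self.final(coarse)

    def zero_residual_branch(self) -> None:
        self.head.zero_out()
        for grp in self.groups:
            for blk in grp:
                blk.expand.zero_out()
                blk.project.zero_out()
        self.deep_tail.zero_out()

    def forward_array(self, lr: np.ndarray) -> np.ndarray:
        """Plain-array forward: (H, W, D, 3) -> (sH, sW, sD, 3)."""
        x = Tensor(np.moveaxis(lr, -1, 0)[None])
        out = self(x)
        return np.moveaxis(out.data[0], 0, -1)


def build_model(cfg: ModelConfig, seed: int = 0) -> SRFlowNet:
    """Deterministic network construction from config and init seed."""
    return SRFlowNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# voxel shuffle as a plain array op
# ---------------------------------------------------------------------------


def voxel_shuffle(feat: np.ndarray, s: int) -> np.ndarray:
    """(s^3 C, H, W, D) -> (C, sH, sW, sD); channel c*s^3 + a*s^2 + b*s + e
    lands at spatial offset (a, b, e) of output channel c."""
    C3, H, W, D = feat.shape
    if C3 % s**3:
        raise ValueError(f"channels {C3} not divisible by s^3 = {s**3}")
    C = C3 // s**3
    t = feat.reshape(C, s, s, s, H, W, D)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3)
    return t.reshape(C, s * H, s * W, s * D)


def inverse_voxel_shuffle(feat: np.ndarray, s: int) -> np.ndarray:
    """Exact inverse of :func:`voxel_shuffle`."""
    C, sH, sW, sD = feat.shape
    if sH % s or sW % s or sD % s:
        raise ValueError("spatial dims not divisible by s")
    H, W, D = sH // s, sW // s, sD // s
    t = feat.reshape(C, H, s, W, s, D, s)
    t = t.transpose(0, 2, 4, 6, 1, 3, 5)
    return t.reshape(C * s**3, H, W, D)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def infer(
    net: SRFlowNet,
    lr: np.ndarray,
    tile_shape: Optional[Sequence[int]] = None,
    overlap: int = 4,
) -> np.ndarray:
    """Apply the network to a normalized LR volume, optionally tiled.

    Adjacent tiles share ``overlap`` LR voxels; half the overlap is
    trimmed from each interior tile face (where zero padding corrupts the
    convolutions) before the remaining cores are averaged into the output.
    ``overlap//2`` must cover the receptive-field halo on the LR grid
    (one voxel per 3x3x3 convolution along any path; 6-8 is ample for the
    default depths).
    """
    s = net.cfg.scale
    if tile_shape is None:
        return net.forward_array(lr)
    tile_shape = tuple(int(t) for t in tile_shape)
    trim = overlap // 2
    if any(t <= 2 * trim for t in tile_shape):
        raise ValueError("tile smaller than twice the trim margin")
    shape = lr.shape[:3]
    out = np.zeros(tuple(s * n for n in shape) + (3,))
    weight = np.zeros(tuple(s * n for n in shape))
    starts = []
    for n, t in zip(shape, tile_shape):
        t = min(t, n)
        step = max(t - overlap, 1)
        axis_starts = list(range(0, max(n - t, 0) + 1, step))
        if axis_starts[-1] != n - t:
            axis_starts.append(n - t)
        starts.append(axis_starts)
    for i0 in starts[0]:
        for j0 in starts[1]:
            for k0 in starts[2]:
                origin = (i0, j0, k0)
                sl = tuple(
                    slice(o, min(o + t, n))
                    for o, t, n in zip(origin, tile_shape, shape)
                )
                pred = net.forward_array(lr[sl])
                # core: drop the padding-corrupted halo on interior faces
                lo = [trim if a.start > 0 else 0 for a in sl]
                hi = [
                    (a.stop - a.start) - (trim if a.stop < n else 0)
                    for a, n in zip(sl, shape)
                ]
                core = tuple(slice(s * l, s * h) for l, h in zip(lo, hi))
                hsl = tuple(
                    slice(s * (a.start + l), s * (a.start + h))
                    for a, l, h in zip(sl, lo, hi)
                )
                out[hsl] += pred[core]
                weight[hsl] += 1.0
    return out / weight[..., None]


# ---------------------------------------------------------------------------
# cubic spline baseline
# ---------------------------------------------------------------------------


def _spline_refine_axis(arr: np.ndarray, s: int, axis: int) -> np.ndarray:
    n = arr.shape[axis]
    spline = CubicSpline(np.arange(n), arr, axis=axis, extrapolate=True)
    return spline(np.arange(n * s) / s)


def cubic_spline_upsample(field, s: int):
    """Tensor-product cubic-spline upsampling by factor s per axis.

    Uses not-a-knot cubic splines axis-by-axis with the corner-aligned
    grid mapping of the k-space degradation model (HR index n sits at LR
    coordinate n/s); the top boundary is spline-extrapolated.  Reproduces
    constant and linear fields exactly.
    """
    if s < 1:
        raise ValueError("scale must be >= 1")
    is_field = isinstance(field, VelocityField)
    data = field.data if is_field else np.asarray(field, dtype=np.float64)
    if s > 1:
        for axis in range(3):
            data = _spline_refine_axis(data, s, axis)
    else:
        data = data.copy()
    if is_field:
        return field.replace(data=data, spacing=field.spacing / s, mask=None)
    return data


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class CubicSplineUpsampler(BaseEstimator):
    """Stateless spline-upsampling baseline with the estimator interface."""

    def __init__(self, scale: int = 2):
        self.scale = scale

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 4
        if single:
            X = X[None]
        out = np.stack([cubic_spline_upsample(x, self.scale) for x in X])
        return out[0] if single else out

    transform = predict


class SRFlowRegressor(BaseEstimator):
    """Learned velocity-field super-resolver (scikit-learn style).

    ``fit(X, y)`` takes aligned low-/high-resolution volume arrays of
    shape (n, h, w, d, 3) and (n, s h, s w, s d, 3) in physical units;
    patches are drawn on the fly each epoch, inputs are normalized to
    [-1, 1] by the training v_max, and optimization is ADAM with a
    staircase learning-rate decay.  When validation volumes are passed,
    the epoch with the best validation PVNR is kept.

    Fitted attributes: ``net_``, ``v_max_``, ``history_`` (dict with
    per-epoch ``loss`` and ``val_pvnr``), ``best_epoch_``, ``n_parameters_``.
    """

    def __init__(
        self,
        scale: int = 2,
        base_channels: int = 32,
        n_groups: int = 4,
        blocks_per_group: int = 2,
        expansion: int = 32,
        se_reduction: int = 8,
        variant: str = "srflow",
        weight_norm: bool = True,
        loss: str = "opt",
        lambda_l1: Optional[float] = None,
        lambda_mp: Optional[float] = None,
        lambda_div: Optional[float] = None,
        epochs: int = 200,
        batch_size: int = 4,
        learning_rate: float = 1e-3,
        lr_decay: float = 0.9,
        decay_every: int = 10,
        patches_per_epoch: int = 500,
        patch_shape: Optional[Tuple[int, int, int]] = None,
        random_state: int = 0,
    ):
        self.scale = scale
        self.base_channels = base_channels
        self.n_groups = n_groups
        self.blocks_per_group = blocks_per_group
        self.expansion = expansion
        self.se_reduction = se_reduction
        self.variant = variant
        self.weight_norm = weight_norm
        self.loss = loss
        self.lambda_l1 = lambda_l1
        self.lambda_mp = lambda_mp
        self.lambda_div = lambda_div
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.patches_per_epoch = patches_per_epoch
        self.patch_shape = patch_shape
        self.random_state = random_state

    # -- config helpers -----------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            base_channels=self.base_channels,
            n_groups=self.n_groups,
            blocks_per_group=self.blocks_per_group,
            expansion=self.expansion,
            se_reduction=self.se_reduction,
            scale=self.scale,
            weight_norm=self.weight_norm,
            variant=self.variant,
        )

    def _loss_config(self) -> LossConfig:
        if self.loss not in LOSS_PRESETS:
            raise ValueError(
                f"unknown loss {self.loss!r}; choose from {sorted(LOSS_PRESETS)}"
            )
        kw = dict(LOSS_PRESETS[self.loss])
        for name in ("lambda_l1", "lambda_mp", "lambda_div"):
            override = getattr(self, name)
            if override is not None:
                kw[name] = override
        return LossConfig(**kw)

    def _resolve_patch_shape(self, lr_shape) -> Tuple[int, int, int]:
        want = self.patch_shape or DEFAULT_PATCH_SHAPES.get(self.scale, (12, 12, 6))
        return tuple(min(int(w), int(n)) for w, n in zip(want, lr_shape))

    def epoch_learning_rate(self, epoch: int) -> float:
        """Staircase schedule: lr multiplied by lr_decay every decay_every
        epochs (epochs numbered from 1)."""
        return self.learning_rate * self.lr_decay ** ((epoch - 1) // self.decay_every)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        from .metrics import pvnr  # local import to avoid a cycle

        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 5 or X.shape[-1] != 3 or y.ndim != 5 or y.shape[-1] != 3:
            raise ValueError("X and y must have shape (n, H, W, D, 3)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must hold the same number of volumes")
        s = self.scale
        if tuple(np.asarray(X.shape[1:4]) * s) != y.shape[1:4]:
            raise ValueError("y spatial shape must be scale x X spatial shape")

        loss_cfg = self._loss_config()
        self.v_max_ = float(np.sqrt((y**2).sum(axis=-1)).max())
        if self.v_max_ <= 0:
            raise ValueError("reference volumes are identically zero")
        Xn = X / self.v_max_
        yn = y / self.v_max_

        rng = np.random.default_rng(self.random_state)
        self.net_ = build_model(
            self._model_config(), seed=int(rng.integers(2**31))
        )
        warm = getattr(self, "_warm_start_params", None)
        if warm is not None:
            for p, saved in zip(self.net_.parameters(), warm):
                p.data[...] = saved
        self.n_parameters_ = self.net_.n_parameters()
        opt = Adam(self.net_.parameters(), lr=self.learning_rate)
        patch = self._resolve_patch_shape(X.shape[1:4])
        steps = max(1, self.patches_per_epoch // self.batch_size)

        history = {"loss": [], "val_pvnr": []}
        best = (-np.inf, None, None)  # (pvnr, epoch, params)
        for epoch in range(1, self.epochs + 1):
            opt.lr = self.epoch_learning_rate(epoch)
            epoch_losses = []
            for _ in range(steps):
                lr_b = np.empty((self.batch_size, 3) + patch)
                hr_b = np.empty(
                    (self.batch_size, 3) + tuple(s * p for p in patch)
                )
                for b in range(self.batch_size):
                    vi = int(rng.integers(X.shape[0]))
                    origin = tuple(
                        int(rng.integers(0, n - p + 1))
                        for n, p in zip(X.shape[1:4], patch)
                    )
                    lsl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
                    hsl = tuple(
                        slice(s * o, s * (o + p)) for o, p in zip(origin, patch)
                    )
                    lr_b[b] = np.moveaxis(Xn[vi][lsl], -1, 0)
                    hr_b[b] = np.moveaxis(yn[vi][hsl], -1, 0)
                pred = self.net_(Tensor(lr_b))
                loss = combined_loss_t(pred, hr_b, loss_cfg)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss.item()}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            history["loss"].append(float(np.mean(epoch_losses)))

            if X_val is not None:
                vals = []
                for lv, hv in zip(np.asarray(X_val), np.asarray(y_val)):
                    pred = self.net_.forward_array(lv / self.v_max_) * self.v_max_
                    vals.append(pvnr(pred, hv))
                vp = float(np.mean(vals))
                history["val_pvnr"].append(vp)
                if vp > best[0]:
                    best = (vp, epoch, [p.data.copy() for p in self.net_.parameters()])

        if best[2] is not None:
            for p, saved in zip(self.net_.parameters(), best[2]):
                p.data[...] = saved
            self.best_epoch_ = best[1]
        else:
            self.best_epoch_ = self.epochs
        self.history_ = history
        return self

    def predict(self, X, tile_shape=None, overlap: int = 4) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 4
        if single:
            X = X[None]
        out = np.stack(
            [
                infer(self.net_, x / self.v_max_, tile_shape, overlap) * self.v_max_
                for x in X
            ]
        )
        return out[0] if single else out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path: str, est: SRFlowRegressor, metadata: dict = None) -> None:
    """Single-file archive: estimator params + network weights + metadata."""
    meta = {
        "params": est.get_params(),
        "v_max": est.v_max_,
        "best_epoch": est.best_epoch_,
        "history": est.history_,
        "metadata": metadata or {},
    }
    arrays = {
        f"param_{i}": p.data for i, p in enumerate(est.net_.parameters())
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> SRFlowRegressor:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"param_{i}"] for i in range(len(z.files) - 1)]
    params = meta["params"]
    if params.get("patch_shape") is not None:
        params["patch_shape"] = tuple(params["patch_shape"])
    est = SRFlowRegressor(**params)
    est.net_ = build_model(est._model_config(), seed=0)
    for p, a in zip(est.net_.parameters(), arrays):
        p.data = np.array(a, dtype=np.float64)
    est.v_max_ = float(meta["v_max"])
    est.best_epoch_ = meta["best_epoch"]
    est.history_ = meta["history"]
    est.n_parameters_ = est.net_.n_parameters()
    return est
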