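"""Network building blocks on top of the autodiff core.

Every layer owns its parameters as ``Tensor(requires_grad=True)`` leaves
and exposes them through ``parameters()`` for the optimizer and for
checkpointing.  Convolutions default to weight normalization
(w = g * v / ||v|| per output channel), which the wide-activation
super-resolution lineage uses in place of batch normalization.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .autograd import Tensor, conv3d, dense, voxel_shuffle_t

__all__ = ["Module", "Conv3d", "SEBlock", "ResidualBlock"]


class Module:
    """Minimal parameter container."""

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv3d(Module):
    """Same-padding 3D convolution with optional weight normalization."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        rng: np.random.Generator,
        weight_norm: bool = True,
    ):
        fan_in = cin * kernel**3
        w0 = rng.standard_normal((cout, cin, kernel, kernel, kernel))
        w0 *= np.sqrt(2.0 / fan_in)
        self.weight_norm = weight_norm
        if weight_norm:
            self.v = Tensor(w0, requires_grad=True)
            norms = np.sqrt((w0**2).sum(axis=(1, 2, 3, 4), keepdims=True))
            self.g = Tensor(norms, requires_grad=True)
        else:
            self.w = Tensor(w0, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def effective_weight(self) -> Tensor:
        if not self.weight_norm:
            return self.w
        norm = self.v.square().sum(axis=(1, 2, 3, 4), keepdims=True)
        return self.v * (self.g / norm.sqrt_safe(1e-12))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.effective_weight(), self.b)

    def zero_out(self) -> None:
        """Make the layer output identically zero (used to ablate a branch).

        With weight normalization only the per-channel gains and biases are
        zeroed; zeroing the direction vectors would make w = g v/||v||
        undefined.
        """
        if self.weight_norm:
            self.g.data[...] = 0.0
        else:
            self.w.data[...] = 0.0
        self.b.data[...] = 0.0


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Global average pool -> dense C -> C/r -> ReLU -> dense C/r -> C ->
    sigmoid; the resulting per-channel gate in (0, 1) rescales the input.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ValueError(
                f"channels {channels} not divisible by reduction {reduction}"
            )
        mid = channels // reduction
        self.w1 = Tensor(
            rng.standard_normal((channels, mid)) * np.sqrt(2.0 / channels),
            requires_grad=True,
        )
        self.b1 = Tensor(np.zeros(mid), requires_grad=True)
        self.w2 = Tensor(
            rng.standard_normal((mid, channels)) * np.sqrt(2.0 / mid),
            requires_grad=True,
        )
        self.b2 = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C = x.shape[:2]
        n_spatial = int(np.prod(x.shape[2:]))
        pooled = x.sum(axis=(2, 3, 4)) * (1.0 / n_spatial)  # (B, C)
        h = dense(pooled, self.w1, self.b1).relu()
        gate = dense(h, self.w2, self.b2).sigmoid()
        return x * gate.reshape(B, C, 1, 1, 1)


class ResidualBlock(Module):
    """Wide-activation residual block, optionally with an SE gate.

    1x1x1 widening convolution C -> pC, ReLU, 3x3x3 convolution pC -> C,
    SE recalibration, additive identity skip.
    """

    def __init__(
        self,
        channels: int,
        expansion: int,
        se_reduction: Optional[int],
        rng: np.random.Generator,
        weight_norm: bool = True,
    ):
        wide = channels * expansion
        self.expand = Conv3d(channels, wide, 1, rng, weight_norm)
        self.project = Conv3d(wide, channels, 3, rng, weight_norm)
        self.se = (
            SEBlock(channels, se_reduction, rng) if se_reduction else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        h = self.expand(x).relu()
        h = self.project(h)
        if self.se is not None:
            h = self.se(h)
        return x + h
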