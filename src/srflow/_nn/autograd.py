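"""Compact reverse-mode autodiff over NumPy arrays.

Supports exactly the operations the super-resolution networks and their
losses need: broadcast arithmetic, abs/relu/sigmoid/sqrt, reductions,
reshape/transpose, 3D same-padding convolution, channel slicing, dense
layers, and a finite-difference gradient along one axis (for the
divergence regularizer).  Gradients flow only into tensors created with
``requires_grad=True`` (parameters) or derived from them.

Arrays are kept in float64; all ops are vectorized, so training-scale
networks (a few tens of thousands of parameters on small patches) run at
interactive speed on one CPU core.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "conv3d", "dense", "voxel_shuffle_t", "gradient_along"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        self.grad: Optional[np.ndarray] = None
        self._parents: Tuple = tuple(parents) if self.requires_grad else ()

    # -- graph plumbing -----------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("tensor does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p, _ in node._parents:
                    stack.append((p, False))

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib
            if node.grad is None and node is self:
                node.grad = g

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        o = Tensor._lift(other)
        return Tensor(
            self.data + o.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (o, lambda g: _unbroadcast(g, o.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        o = Tensor._lift(other)
        return Tensor(
            self.data * o.data,
            parents=(
                (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._lift(other)
        return Tensor(
            self.data / o.data,
            parents=(
                (self, lambda g: _unbroadcast(g / o.data, self.data.shape)),
                (
                    o,
                    lambda g: _unbroadcast(
                        -g * self.data / o.data**2, o.data.shape
                    ),
                ),
            ),
        )

    # -- elementwise --------------------------------------------------------

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=((self, lambda g: g * sign),))

    def square(self):
        return Tensor(self.data**2, parents=((self, lambda g: 2 * g * self.data),))

    def sqrt_safe(self, eps: float = 1e-12):
        """sqrt with the backward denominator floored at eps."""
        root = np.sqrt(np.maximum(self.data, 0.0))
        denom = np.maximum(root, eps)
        return Tensor(root, parents=((self, lambda g: 0.5 * g / denom),))

    def clip_min(self, lo: float):
        keep = self.data > lo
        return Tensor(
            np.maximum(self.data, lo), parents=((self, lambda g: g * keep),)
        )

    def relu(self):
        keep = self.data > 0
        return Tensor(self.data * keep, parents=((self, lambda g: g * keep),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(s, parents=((self, lambda g: g * s * (1 - s)),))

    # -- reductions / shaping -----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        shape = self.data.shape

        def back(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return np.broadcast_to(gg, shape).copy()

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=((self, back),)
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=((self, lambda g: g.transpose(inv)),),
        )

    def narrow_channel(self, i: int):
        """Select channel i of a (B, C, ...) tensor (axis 1)."""
        shape = self.data.shape

        def back(g):
            out = np.zeros(shape)
            out[:, i] = g
            return out

        return Tensor(self.data[:, i], parents=((self, back),))


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Same-padding, stride-1 3D convolution (cross-correlation).

    x: (B, Cin, H, W, D); w: (Cout, Cin, k, k, k) with odd k; b: (Cout,).
    """
    k = w.data.shape[2]
    pad = k // 2
    B, Cin = x.data.shape[:2]
    spatial = x.data.shape[2:]
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    else:
        xp = x.data
    patches = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # patches: (B, Cin, H, W, D, k, k, k)
    out = np.einsum("bchwdijk,ocijk->bohwd", patches, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None, None]

    def back_x(g):
        # full correlation of g with the flipped, channel-swapped kernel
        wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        if pad:
            gp = np.pad(g, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
        else:
            gp = g
        gpatch = np.lib.stride_tricks.sliding_window_view(
            gp, (k, k, k), axis=(2, 3, 4)
        )
        return np.einsum("bohwdijk,coijk->bchwd", gpatch, wt, optimize=True)

    def back_w(g):
        return np.einsum("bohwd,bchwdijk->ocijk", g, patches, optimize=True)

    parents = [(x, back_x), (w, back_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3, 4))))
    return Tensor(out, parents=parents)


def dense(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """x (B, Cin) @ w (Cin, Cout) + b."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data
    parents = [
        (x, lambda g: g @ w.data.T),
        (w, lambda g: x.data.T @ g),
    ]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=0)))
    return Tensor(out, parents=parents)


def voxel_shuffle_t(x: Tensor, s: int) -> Tensor:
    """(B, s^3 C, H, W, D) -> (B, C, sH, sW, sD) sub-pixel rearrangement.

    Input channel c*s^3 + a*s^2 + b*s + e maps to output channel c at
    spatial offset (a, b, e) within each s-block.
    """
    B, C3, H, W, D = x.data.shape
    if C3 % s**3:
        raise ValueError(f"channel count {C3} not divisible by s^3 = {s**3}")
    C = C3 // s**3
    t = x.reshape(B, C, s, s, s, H, W, D)
    t = t.transpose((0, 1, 5, 2, 6, 3, 7, 4))  # B, C, H, a, W, b, D, e
    return t.reshape(B, C, s * H, s * W, s * D)


def gradient_along(x: Tensor, axis: int, spacing: float = 1.0) -> Tensor:
    """np.gradient-style finite difference along one axis, differentiable.

    Central differences in the interior, one-sided at the two boundary
    planes, divided by ``spacing``.
    """
    data = x.data
    out = np.gradient(data, spacing, axis=axis)
    n = data.shape[axis]
    if n < 2:
        raise ValueError("gradient needs at least 2 samples along the axis")

    def sl(i, j=None):
        idx = [slice(None)] * data.ndim
        idx[axis] = slice(i, j) if j is not None else i
        return tuple(idx)

    def back(g):
        gi = np.zeros_like(data)
        h2 = 2.0 * spacing
        # interior: out[i] = (f[i+1] - f[i-1]) / 2h
        if n > 2:
            gi[sl(2, n)] += g[sl(1, n - 1)] / h2
            gi[sl(0, n - 2)] -= g[sl(1, n - 1)] / h2
        # boundaries: out[0] = (f[1]-f[0])/h ; out[-1] = (f[-1]-f[-2])/h
        gi[sl(1)] += g[sl(0)] / spacing
        gi[sl(0)] -= g[sl(0)] / spacing
        gi[sl(n - 1)] += g[sl(n - 1)] / spacing
        gi[sl(n - 2)] -= g[sl(n - 1)] / spacing
        return gi

    return Tensor(out, parents=((x, back),))
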