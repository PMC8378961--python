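"""Define-by-run reverse-mode autodiff with just enough ops for the network."""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from ..errors import ShapeError
from . import convops

__all__ = [
    "Tensor", "add", "sub", "mul", "scale", "mean", "l1_mean", "concat",
    "conv2d", "conv_transpose2d", "global_avg_pool", "pixel_shuffle",
    "pixel_unshuffle", "prelu", "relu", "sigmoid",
]


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-propagate from this node through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ShapeError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}{tag}, requires_grad={self.requires_grad})"


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(-_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def scale(a: Tensor, c: float) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * c)

    return _node(a.data * c, (a,), bwd)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def bwd(g):
        if a.requires_grad:
            a.accumulate(np.full_like(a.data, float(g) / n))

    return _node(np.asarray(a.data.mean()), (a,), bwd)


def l1_mean(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute difference; subgradient 0 at exact ties."""
    if pred.data.shape != target.data.shape:
        raise ShapeError(
            f"l1_mean shape mismatch: {pred.data.shape} vs {target.data.shape}"
        )
    diff = pred.data - target.data
    n = diff.size

    def bwd(g):
        s = np.sign(diff) * (float(g) / n)
        if pred.requires_grad:
            pred.accumulate(s)
        if target.requires_grad:
            target.accumulate(-s)

    return _node(np.asarray(np.abs(diff).mean()), (pred, target), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return _node(out_data, tuple(ts), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * mask)

    return _node(a.data * mask, (a,), bwd)


def prelu(a: Tensor, alpha: Tensor) -> Tensor:
    """Per-channel parametric rectifier; alpha has shape (C,) for NCHW input."""
    al = alpha.data.reshape(1, -1, 1, 1)
    pos = a.data > 0
    out_data = np.where(pos, a.data, al * a.data)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(np.where(pos, g, al * g))
        if alpha.requires_grad:
            da = np.where(pos, 0.0, a.data * g).sum(axis=(0, 2, 3))
            alpha.accumulate(da)

    return _node(out_data, (a, alpha), bwd)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * s * (1.0 - s))

    return _node(s, (a,), bwd)


def global_avg_pool(a: Tensor) -> Tensor:
    """Spatial mean per channel: (N,C,H,W) -> (N,C,1,1)."""
    _, _, h, w = a.data.shape
    out_data = a.data.mean(axis=(2, 3), keepdims=True)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(np.broadcast_to(g / (h * w), a.data.shape).copy())

    return _node(out_data, (a,), bwd)


def _shuffle(x: np.ndarray, r: int) -> np.ndarray:
    n, crr, h, w = x.shape
    c = crr // (r * r)
    y = x.reshape(n, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(y.reshape(n, c, h * r, w * r))


def _unshuffle(x: np.ndarray, r: int) -> np.ndarray:
    n, c, hr, wr = x.shape
    h, w = hr // r, wr // r
    y = x.reshape(n, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
    return np.ascontiguousarray(y.reshape(n, c * r * r, h, w))


def pixel_shuffle(a: Tensor, r: int) -> Tensor:
    """Rearrange (N, c*r^2, H, W) -> (N, c, rH, rW); a pure value permutation."""
    n, crr, h, w = a.data.shape
    if crr % (r * r):
        raise ShapeError(f"pixel_shuffle: {crr} channels not divisible by {r * r}")

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unshuffle(g, r))

    return _node(_shuffle(a.data, r), (a,), bwd)


def pixel_unshuffle(a: Tensor, r: int) -> Tensor:
    """Exact inverse of :func:`pixel_shuffle`."""
    n, c, hr, wr = a.data.shape
    if hr % r or wr % r:
        raise ShapeError(f"pixel_unshuffle: spatial dims {hr}x{wr} not divisible by {r}")

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_shuffle(g, r))

    return _node(_unshuffle(a.data, r), (a,), bwd)


def conv2d(
    x: Tensor, w: Tensor, b: Tensor | None = None,
    stride: int = 1, pad: int = 0, dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW x OIHW, optional bias of shape (O,)."""
    if x.data.ndim != 4 or w.data.ndim != 4:
        raise ShapeError("conv2d expects 4-D input and weight")
    if x.data.shape[1] != w.data.shape[1]:
        raise ShapeError(
            f"conv2d channel mismatch: input {x.data.shape[1]}, weight {w.data.shape[1]}"
        )
    cols = convops.im2col(x.data, w.data.shape[2], w.data.shape[3], stride, pad, dilation)
    out_data = convops.conv_from_cols(cols, w.data)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(
                convops.conv2d_input_grad(g, w.data, x.data.shape, stride, pad, dilation)
            )
        if w.requires_grad:
            w.accumulate(convops.conv2d_weight_grad_cols(cols, g))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0
) -> Tensor:
    """Transposed convolution (adjoint of conv2d); weight shape (C_in, C_out, kh, kw).

    Output spatial size is ``(n - 1) * stride - 2 * pad + k``.
    """
    if x.data.shape[1] != w.data.shape[0]:
        raise ShapeError(
            f"conv_transpose2d channel mismatch: input {x.data.shape[1]}, "
            f"weight {w.data.shape[0]}"
        )
    n, _, h, wd = x.data.shape
    c_out, kh, kw = w.data.shape[1], w.data.shape[2], w.data.shape[3]
    out_shape = (
        n, c_out, (h - 1) * stride - 2 * pad + kh, (wd - 1) * stride - 2 * pad + kw
    )
    out_data = convops.conv2d_input_grad(x.data, w.data, out_shape, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(convops.conv2d_forward(g, w.data, stride, pad))
        if w.requires_grad:
            w.accumulate(
                convops.conv2d_weight_grad(g, x.data, w.data.shape, stride, pad)
            )
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)
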