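"""Raw numpy 2-D convolution kernels (forward + both gradients).

Layout: activations NCHW, weights OIHW.  The forward path materializes an
im2col block of shape (N, Ho, Wo, C, kh, kw); callers may keep it and pass it
back to :func:`conv2d_weight_grad_cols` so backward reuses the gather.  The
input gradient accumulates per kernel tap in NHWC layout to avoid a
kh*kw-times-larger temporary.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_out_size",
    "im2col",
    "conv_from_cols",
    "conv2d_forward",
    "conv2d_input_grad",
    "conv2d_weight_grad",
    "conv2d_weight_grad_cols",
]


def conv_out_size(n: int, k: int, stride: int, pad: int, dilation: int = 1) -> int:
    return (n + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def _pad(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def im2col(
    x: np.ndarray, kh: int, kw: int, stride: int = 1, pad: int = 0, dilation: int = 1
) -> np.ndarray:
    """Contiguous (N, Ho, Wo, C, kh, kw) window block of the padded input."""
    xp = _pad(x, pad)
    span_h = dilation * (kh - 1) + 1
    span_w = dilation * (kw - 1) + 1
    v = sliding_window_view(xp, (span_h, span_w), axis=(2, 3))
    v = v[:, :, ::stride, ::stride, ::dilation, ::dilation]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))


def conv_from_cols(cols: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(N,Ho,Wo,C,kh,kw) x (O,C,kh,kw) -> (N,O,Ho,Wo)."""
    out = np.tensordot(cols, w, axes=([3, 4, 5], [1, 2, 3]))
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d_forward(
    x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0, dilation: int = 1
) -> np.ndarray:
    """Cross-correlation of x (N,C,H,W) with w (O,C,kh,kw)."""
    assert x.shape[1] == w.shape[1], f"channel mismatch {x.shape[1]} vs {w.shape[1]}"
    return conv_from_cols(im2col(x, w.shape[2], w.shape[3], stride, pad, dilation), w)


def conv2d_input_grad(
    dy: np.ndarray,
    w: np.ndarray,
    x_shape: tuple[int, ...],
    stride: int = 1,
    pad: int = 0,
    dilation: int = 1,
) -> np.ndarray:
    """Gradient of conv2d_forward w.r.t. its input (the adjoint operator)."""
    n, c, h, wid = x_shape
    o, _, kh, kw = w.shape
    _, _, ho, wo = dy.shape
    dyt = dy.transpose(0, 2, 3, 1)  # (N,Ho,Wo,O)
    dxp = np.zeros((n, h + 2 * pad, wid + 2 * pad, c), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            t = np.tensordot(dyt, w[:, :, i, j], axes=([3], [0]))  # (N,Ho,Wo,C)
            dxp[
                :,
                i * dilation : i * dilation + stride * (ho - 1) + 1 : stride,
                j * dilation : j * dilation + stride * (wo - 1) + 1 : stride,
                :,
            ] += t
    dx = dxp.transpose(0, 3, 1, 2)
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(dx)


def conv2d_weight_grad_cols(cols: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Weight gradient from a kept im2col block: -> (O,C,kh,kw)."""
    return np.tensordot(dy, cols, axes=([0, 2, 3], [0, 1, 2]))


def conv2d_weight_grad(
    x: np.ndarray,
    dy: np.ndarray,
    w_shape: tuple[int, ...],
    stride: int = 1,
    pad: int = 0,
    dilation: int = 1,
) -> np.ndarray:
    """Gradient of conv2d_forward w.r.t. the weight."""
    o, c, kh, kw = w_shape
    return conv2d_weight_grad_cols(im2col(x, kh, kw, stride, pad, dilation), dy)
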