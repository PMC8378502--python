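"""Convolution primitives shared by the recurrent cells.

Convolutions are implemented as im2col + matmul so that the forward pass
and the analytic gradients with respect to both the kernel and the input
reuse a single, easily testable code path.  All spatial dims are preserved
with symmetric zero padding (kernels must have odd size).
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def im2col(x: np.ndarray, kernel_size: int) -> np.ndarray:
    """Unfold ``x`` of shape (B, C, H, W) into patches (B, H*W, C*k*k)."""
    k = kernel_size
    if k % 2 != 1:
        raise ValueError(f"kernel_size must be odd, got {k}")
    p = k // 2
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H*W, C*k*k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * k * k)
    return np.ascontiguousarray(cols)


def col2im(cols: np.ndarray, x_shape: tuple[int, int, int, int], kernel_size: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back to (B, C, H, W)."""
    k = kernel_size
    p = k // 2
    b, c, h, w = x_shape
    g = cols.reshape(b, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)  # (B, C, k, k, H, W)
    xp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + h, kj:kj + w] += g[:, :, ki, kj]
    return xp[:, :, p:p + h, p:p + w]


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Same-padded 2-D convolution (cross-correlation), x (B,C,H,W), weight (Cout,Cin,k,k)."""
    b, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {cin}")
    cols = im2col(x, k)                       # (B, HW, C*k*k)
    wmat = weight.reshape(cout, cin * k * k)  # (Cout, C*k*k)
    out = cols @ wmat.T                       # (B, HW, Cout)
    if bias is not None:
        out = out + bias
    return out.transpose(0, 2, 1).reshape(b, cout, h, w)
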