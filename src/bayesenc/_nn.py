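"""Minimal numpy neural-network engine.

Implements exactly what the encoders need: valid (no-padding, stride-1)
2-D convolution via im2col, ReLU, inverted dropout, a fully connected layer,
and the Adam optimizer — each with hand-derived backward passes.  Gradient
correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

# Pre-activation clamp before the exponential output nonlinearity.  exp(20)
# ~ 5e8 comfortably exceeds any realistic firing rate while keeping
# gradients finite during early training.
Z_CLIP = 20.0


def conv_out_hw(in_hw, kernel_hw):
    """Valid-convolution output size: out = in - k + 1 per axis."""
    oh = in_hw[0] - kernel_hw[0] + 1
    ow = in_hw[1] - kernel_hw[1] + 1
    return oh, ow


def im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, H, W) -> (B, oh*ow, C*kh*kw) patch matrix for valid conv."""
    b, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"kernel ({kh},{kw}) larger than input ({h},{w})")
    # windows: (B, C, oh, ow, kh, kw)
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols)


def col2im(grad_cols: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back to input."""
    b, c, h, w = x_shape
    oh, ow = h - kh + 1, w - kw + 1
    gc = grad_cols.reshape(b, oh, ow, c, kh, kw)
    gx = np.zeros(x_shape, dtype=grad_cols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + oh, j : j + ow] += gc[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return gx


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Valid conv, stride 1.  weight: (Cout, Cin, kh, kw), bias: (Cout,).

    Returns (output (B, Cout, oh, ow), cache).
    """
    cout, cin, kh, kw = weight.shape
    b = x.shape[0]
    oh, ow = conv_out_hw(x.shape[2:], (kh, kw))
    cols = im2col(x, kh, kw)  # (B, P, Cin*kh*kw)
    wmat = weight.reshape(cout, -1)  # (Cout, Cin*kh*kw)
    out = cols @ wmat.T + bias  # (B, P, Cout)
    out = out.transpose(0, 2, 1).reshape(b, cout, oh, ow)
    cache = (cols, wmat, x.shape, weight.shape)
    return out, cache


def conv_backward(grad_out: np.ndarray, cache, need_input_grad: bool = True):
    """Gradients of a valid conv: returns (grad_x, grad_weight, grad_bias).

    ``need_input_grad=False`` skips the costly col2im scatter (the input
    gradient is only needed for MEI synthesis, not for weight training of
    the first layer).
    """
    cols, wmat, x_shape, w_shape = cache
    cout, cin, kh, kw = w_shape
    b = grad_out.shape[0]
    g = grad_out.reshape(b, cout, -1).transpose(0, 2, 1)  # (B, P, Cout)
    g2 = np.ascontiguousarray(g).reshape(-1, cout)
    grad_w = (g2.T @ cols.reshape(-1, cols.shape[-1])).reshape(w_shape)
    grad_b = g2.sum(axis=0)
    grad_x = None
    if need_input_grad:
        grad_cols = g @ wmat  # (B, P, Cin*kh*kw)
        grad_x = col2im(grad_cols, x_shape, kh, kw)
    return grad_x, grad_w, grad_b


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(grad_out, mask):
    return grad_out * mask


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout mask: zeros with prob ``rate``, else 1/(1-rate)."""
    if rate == 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def fc_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """x: (B, F), weight: (N, F), bias: (N,) -> (B, N)."""
    return x @ weight.T + bias, x


def fc_backward(grad_out: np.ndarray, x: np.ndarray, weight: np.ndarray):
    grad_w = grad_out.T @ x
    grad_b = grad_out.sum(axis=0)
    grad_x = grad_out @ weight
    return grad_x, grad_w, grad_b


def exp_forward(z: np.ndarray):
    """Clamped exponential output nonlinearity (keeps rates finite)."""
    zc = np.clip(z, -Z_CLIP, Z_CLIP)
    out = np.exp(zc)
    inside = (z > -Z_CLIP) & (z < Z_CLIP)
    return out, (out, inside)


def exp_backward(grad_out: np.ndarray, cache):
    out, inside = cache
    return grad_out * out * inside


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place)."""

    def __init__(self, params: dict, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
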