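"""Minimal CNN engine (forward/backward in numpy) used by the detector.

Implements only what the detector architecture needs: same-padded 3x3
convolutions via im2col, ReLU, batch normalization, 2x2 max pooling,
dropout, dense layers, a class-weighted binary cross-entropy on logits,
and an Adam optimizer. float32 throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import special

EPS = 1e-5


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


# ---------------------------------------------------------------- conv ----

def _shifted(xp: np.ndarray, di: int, dj: int, h: int, w: int) -> np.ndarray:
    """One 3x3-offset view of the padded input, flattened to (N*H*W, C)."""
    n, _, _, c = xp.shape
    return xp[:, di : di + h, dj : dj + w, :].reshape(n * h * w, c)


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 conv as nine accumulated matmuls; w: (3,3,Cin,Cout).

    Avoids materializing a 9x-inflated im2col matrix, which dominates
    runtime on a single core; each shifted slice is copied once and fed to
    a small-k GEMM instead.
    """
    n, h, wd, cin = x.shape
    cout = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.tile(b.astype(x.dtype), (n * h * wd, 1))
    for di in range(3):
        for dj in range(3):
            out += _shifted(xp, di, dj, h, wd) @ w[di, dj]
    return out.reshape(n, h, wd, cout), (xp, x.shape, w)


def conv2d_backward(dout: np.ndarray, cache):
    xp, x_shape, w = cache
    n, h, wd, cin = x_shape
    cout = w.shape[-1]
    dflat = dout.reshape(n * h * wd, cout)
    dw = np.empty_like(w)
    for di in range(3):
        for dj in range(3):
            dw[di, dj] = _shifted(xp, di, dj, h, wd).T @ dflat
    db = dflat.sum(axis=0)
    # gradient w.r.t. input = conv of dout with spatially-rotated kernels
    dp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dx = np.zeros((n * h * wd, cin), dtype=dout.dtype)
    for di in range(3):
        for dj in range(3):
            # rotated kernel: w[2-di, 2-dj] transposed to (Cout, Cin)
            dx += _shifted(dp, di, dj, h, wd) @ w[2 - di, 2 - dj].T
    return dx.reshape(x_shape), dw, db


# ---------------------------------------------------------------- misc ----

def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    """2x2/stride-2 max pool; odd trailing rows/cols are dropped."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2]
    xr = (
        xc.reshape(n, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2, w2, c, 4)
    )
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dxr = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxc = dxr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
        n, h2 * 2, w2 * 2, c
    )
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : h2 * 2, : w2 * 2] = dxc
    return dx


def batchnorm_forward(x, gamma, beta, running, training: bool, momentum=0.9):
    """Normalizes over all axes but the last (channel) axis."""
    axes = tuple(range(x.ndim - 1))
    if training:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    std = np.sqrt(var + EPS)
    xhat = (x - mean) / std
    return gamma * xhat + beta, (xhat, std, gamma, axes)


def batchnorm_backward(dout, cache):
    xhat, std, gamma, axes = cache
    m = np.prod([dout.shape[a] for a in axes])
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dx = (gamma / (std * m)) * (
        m * dout - dbeta - xhat * dgamma
    )
    return dx.astype(dout.dtype), dgamma, dbeta


def dropout_forward(x, rate: float, rng: np.random.Generator, training: bool):
    if not training or rate <= 0:
        return x, None
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(dout, mask):
    return dout if mask is None else dout * mask


def weighted_bce_with_logits(logits, y, pos_weight: float):
    """Mean class-weighted binary cross-entropy; returns (loss, dlogits)."""
    z = logits.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    softplus = np.logaddexp(0.0, z)
    loss_i = pos_weight * y * (softplus - z) + (1 - y) * softplus
    p = special.expit(z)
    dz = (pos_weight * y * (p - 1) + (1 - y) * p) / z.size
    return float(loss_i.mean()), dz.astype(np.float32).reshape(logits.shape)


class Adam:
    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )
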