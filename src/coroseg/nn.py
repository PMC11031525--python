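"""Minimal CPU neural-network engine: 2D convolutions, pooling, attention
gates and Adam, with hand-written backpropagation on numpy arrays.

Layers are single-use per forward pass: each ``forward`` caches what its
``backward`` needs, and ``backward`` consumes that cache.  Convolutions are
lowered to matrix multiplication via im2col so the heavy lifting runs in
BLAS.  Arrays are float32 throughout; activations use the NCHW layout.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)

    @property
    def size(self) -> int:
        return self.v.size


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


class Conv2d:
    """Stride-1 convolution with 'same' zero padding (kernel 3) or 1x1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        assert kernel in (1, 3)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))  # He init for ReLU nets
        self.W = Param(rng.standard_normal((c_out, c_in, kernel, kernel)) * scale)
        self.b = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        wmat = self.W.v.reshape(self.c_out, -1)
        y = cols @ wmat.T
        if self.b is not None:
            y += self.b.v
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        self._cache = None
        n, c, h, w = x_shape
        dy_col = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.W.g += (dy_col.T @ cols).reshape(self.W.v.shape)
        if self.b is not None:
            self.b.g += dy_col.sum(axis=0)
        # dx is a conv of dy with the spatially flipped, channel-transposed kernel
        wback = self.W.v[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, -1)
        dcols = _im2col(dy, self.k, self.pad)
        dx = dcols @ wback.T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        m, self._mask = self._mask, None
        return np.where(m, dy, 0.0)


class MaxPool2:
    """2x2 max pooling; ties send the gradient to the first maximal entry."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        self._cache = None
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class UpNearest2:
    """2x nearest-neighbour upsampling."""

    def params(self):
        return []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy over all channels/pixels, with gradient.

    Returns ``(loss, dlogits)``; the sigmoid is fused for numerical stability.
    """
    z = logits.astype(np.float64, copy=False)
    t = targets
    loss = float(np.mean(np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    p = sigmoid(logits)
    dlogits = (p - t).astype(logits.dtype, copy=False) / logits.size
    return loss, dlogits


class ConvBlock:
    """Two 3x3 conv + ReLU stages, the standard U-Net building block."""

    def __init__(self, c_in, c_out, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.relu2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(dy))))


class AttentionGate:
    """Additive attention gate on a skip connection.

    Given skip features ``s`` and a same-resolution gating signal ``g`` from
    the decoder, computes a one-channel mask
    ``psi = sigma(w_psi . relu(W_x s + W_g g))`` and returns ``s * psi``,
    suppressing skip activations outside the region the decoder attends to.
    """

    def __init__(self, channels, rng):
        c_int = max(channels // 2, 1)
        self.wx = Conv2d(channels, c_int, 1, rng, bias=False)
        self.wg = Conv2d(channels, c_int, 1, rng, bias=True)
        self.psi = Conv2d(c_int, 1, 1, rng, bias=True)
        self.relu = ReLU()
        self._cache = None

    def params(self):
        return self.wx.params() + self.wg.params() + self.psi.params()

    def forward(self, s, g):
        q = self.relu.forward(self.wx.forward(s) + self.wg.forward(g))
        alpha = sigmoid(self.psi.forward(q))
        self._cache = (s, alpha)
        return s * alpha

    def backward(self, dy):
        s, alpha = self._cache
        self._cache = None
        ds = dy * alpha
        dalpha = (dy * s).sum(axis=1, keepdims=True)
        dpsi_in = self.psi.backward(dalpha * alpha * (1.0 - alpha))
        dq = self.relu.backward(dpsi_in)
        ds += self.wx.backward(dq)
        dg = self.wg.backward(dq)
        return ds, dg


class Adam:
    """Adam optimiser with bias correction over a list of Params."""

    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.g
            v *= self.b2
            v += (1.0 - self.b2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
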