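"""Layers with explicit forward/backward passes.

Convolutions are 'same'-padded, stride 1, implemented as k*k shifted matrix
multiplications — memory-light and fast enough for the small segmentation and
embedding networks used here.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding, with bias.

    Weight shape (k, k, c_in, c_out); parameter count k*k*c_in*c_out + c_out.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * c_in))
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.W = Param((rng.standard_normal((k, k, c_in, c_out)) * std).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ymat = np.broadcast_to(self.b.value, (n * h * w, self.c_out)).copy()
        Wv = self.W.value
        for i in range(self.k):
            for j in range(self.k):
                patch = xp[:, :, i:i + h, j:j + w]
                flat = patch.transpose(0, 2, 3, 1).reshape(-1, self.c_in)
                ymat += flat @ Wv[i, j]
        self._cache = (xp, x.shape)
        return ymat.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, (n, c, h, w) = self._cache
        p = self.k // 2
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.b.grad += g.sum(axis=0)
        dxp = np.zeros_like(xp)
        Wv = self.W.value
        for i in range(self.k):
            for j in range(self.k):
                patch = xp[:, :, i:i + h, j:j + w]
                flat = patch.transpose(0, 2, 3, 1).reshape(-1, self.c_in)
                self.W.grad[i, j] += flat.T @ g
                dflat = g @ Wv[i, j].T
                dxp[:, :, i:i + h, j:j + w] += dflat.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class InstanceNorm2d(Layer):
    """Per-channel spatial normalization with learnable affine parameters.

    Normalizes each channel of each sample over its spatial extent —
    the batch-size-independent choice for segmentation nets trained with
    single-frame batches.
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float64):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        return (self._xhat * g + b).astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.value[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        # d/dx of (x - mu) / sqrt(var + eps) over the spatial axes
        term = gxhat - gxhat.mean(axis=(2, 3), keepdims=True) \
            - xhat * (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return (term * inv).astype(grad.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even H and W")
        xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xw = xw.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xw.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xw, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxw = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxw, self._idx[..., None], grad[..., None], axis=-1)
        dxw = dxw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxw.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class AdaptiveAvgPool(Layer):
    """Average-pool to a fixed (gh, gw) grid; spatial dims must be divisible."""

    def __init__(self, gh: int, gw: int):
        self.gh, self.gw = gh, gw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % self.gh or w % self.gw:
            raise ValueError("spatial dims must divide the pooling grid")
        self._shape = x.shape
        bh, bw = h // self.gh, w // self.gw
        return x.reshape(n, c, self.gh, bh, self.gw, bw).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        bh, bw = h // self.gh, w // self.gw
        g = grad[:, :, :, None, :, None] / (bh * bw)
        return np.broadcast_to(g, (n, c, self.gh, bh, self.gw, bw)).reshape(n, c, h, w)


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / f_in)
        self.W = Param((rng.standard_normal((f_in, f_out)) * std).astype(dtype))
        self.b = Param(np.zeros(f_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def softmax_cross_entropy(logits: np.ndarray, classes: np.ndarray,
                          weights: np.ndarray | None = None):
    """Per-pixel weighted cross-entropy, averaged over all pixels.

    logits: (N, K, H, W); classes: (N, H, W) integers in [0, K); weights:
    (N, H, W) positive or None (ones). Returns (loss, dloss/dlogits).
    """
    n, k, h, w = logits.shape
    if classes.min() < 0 or classes.max() >= k:
        raise ValueError("class labels outside the logit range")
    if weights is None:
        weights = np.ones((n, h, w), dtype=logits.dtype)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    idx = classes[:, None, :, :]
    p_true = np.take_along_axis(p, idx, axis=1)[:, 0]
    npix = n * h * w
    loss = float((weights * -np.log(np.maximum(p_true, 1e-300))).sum() / npix)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, idx, 1.0, axis=1)
    dlogits = weights[:, None] * (p - onehot) / npix
    return loss, dlogits


def masked_angle_loss(pred_deg: np.ndarray, target_deg: np.ndarray):
    """Circular regression loss sin^2((pred - target)/2), degrees in, radians inside.

    Evaluated on the foreground only (target != -1); 0 on empty foreground.
    Returns (loss, dloss/dpred).
    """
    mask = target_deg != -1
    dpred = np.zeros_like(pred_deg)
    nfg = int(mask.sum())
    if nfg == 0:
        return 0.0, dpred
    delta = np.deg2rad(pred_deg[mask] - target_deg[mask])
    loss = float(np.mean(np.sin(delta / 2.0) ** 2))
    dpred[mask] = 0.5 * np.sin(delta) * (np.pi / 180.0) / nfg
    return loss, dpred
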