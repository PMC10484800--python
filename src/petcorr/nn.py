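"""Minimal NumPy neural-network kernels for 2D image-to-image regression.

Implements exactly what the correction-map predictor needs — strided
convolution, transposed convolution, ReLU, residual blocks, a masked L2 loss
and an Adam optimizer — with explicit, testable forward/backward passes
(im2col/col2im based). Array layout is ``(batch, channels, height, width)``,
float32. This is a deliberately small framework: no autograd graph, each
layer caches what its backward pass needs.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# im2col / col2im

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*k*k, Ho*Wo) patch matrix."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (B,C,Ho,Wo,k,k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, Ho * Wo)
    return np.ascontiguousarray(cols), (Ho, Wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col` (scatter-add of patches back into an image)."""
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    c6 = cols.reshape(B, C, k, k, Ho, Wo)
    xp = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += c6[:, :, i, j]
    return xp[:, :, pad:H + pad, pad:W + pad]


# ---------------------------------------------------------------------------
# layers

class Layer:
    params: list  # list of dicts with keys w, g (same shape)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, c_in, c_out, k=3, stride=1, pad=1, rng=None, w_scale=1.0,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        std = w_scale * np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [{"w": self.W, "g": self.gW}, {"w": self.b, "g": self.gb}]

    def forward(self, x):
        self._x_shape = x.shape
        cols, (Ho, Wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        B = x.shape[0]
        W2 = self.W.reshape(self.W.shape[0], -1)
        out = W2 @ cols + self.b[None, :, None]
        return out.reshape(B, self.W.shape[0], Ho, Wo)

    def backward(self, dy):
        B, Co, Ho, Wo = dy.shape
        dy2 = dy.reshape(B, Co, Ho * Wo)
        W2 = self.W.reshape(Co, -1)
        self.gW[...] = np.matmul(dy2, self._cols.transpose(0, 2, 1)).sum(0).reshape(self.W.shape)
        self.gb[...] = dy2.sum(axis=(0, 2))
        dcols = np.matmul(W2.T, dy2)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2D(Layer):
    """Fractionally-strided convolution; with k=4, stride=2, pad=1 it doubles
    the spatial size (the exact adjoint of the matching strided Conv2D)."""

    def __init__(self, c_in, c_out, k=4, stride=2, pad=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(c_in, c_out, k, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [{"w": self.W, "g": self.gW}, {"w": self.b, "g": self.gb}]

    def _out_shape(self, H, W):
        return ((H - 1) * self.stride - 2 * self.pad + self.k,
                (W - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x):
        B, Ci, H, W = x.shape
        self._x = x
        Ho, Wo = self._out_shape(H, W)
        Co = self.W.shape[1]
        W2 = self.W.reshape(Ci, -1)                    # (Ci, Co*k*k)
        x2 = x.reshape(B, Ci, H * W)
        cols = np.matmul(W2.T, x2)                     # (B, Co*k*k, H*W)
        y = _col2im(cols, (B, Co, Ho, Wo), self.k, self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        B, Ci, H, W = self._x.shape
        cols, _ = _im2col(dy, self.k, self.stride, self.pad)  # (B, Co*k*k, H*W)
        W2 = self.W.reshape(Ci, -1)
        x2 = self._x.reshape(B, Ci, H * W)
        self.gW[...] = np.matmul(x2, cols.transpose(0, 2, 1)).sum(0).reshape(self.W.shape)
        self.gb[...] = dy.sum(axis=(0, 2, 3))
        dx = np.matmul(W2, cols).reshape(B, Ci, H, W)
        return dx


class ReLU(Layer):
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ResidualBlock(Layer):
    """conv3x3 → ReLU → conv3x3, plus identity skip (no activation after the add)."""

    def __init__(self, channels, rng=None, dtype=np.float32):
        self.conv1 = Conv2D(channels, channels, 3, 1, 1, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.conv2 = Conv2D(channels, channels, 3, 1, 1, rng=rng, dtype=dtype)
        self.params = self.conv1.params + self.conv2.params

    def forward(self, x):
        h = self.conv2.forward(self.relu.forward(self.conv1.forward(x)))
        return x + h

    def backward(self, dy):
        dh = self.conv1.backward(self.relu.backward(self.conv2.backward(dy)))
        return dy + dh


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)
        self.params = [p for l in self.layers for p in l.params]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    # checkpointing ---------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p["w"].copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.params):
            raise ValueError("state does not match network parameters")
        for p, w in zip(self.params, state):
            p["w"][...] = w


# ---------------------------------------------------------------------------
# loss and optimizer

def masked_mse(pred: np.ndarray, target: np.ndarray, weight: np.ndarray):
    """Weighted mean squared error and its gradient w.r.t. ``pred``.

    ``weight`` is typically a {0,1} validity mask; voxels with zero weight
    contribute nothing to either the loss or the gradient.
    """
    wsum = float(weight.sum())
    if wsum <= 0:
        return 0.0, np.zeros_like(pred)
    diff = (pred - target) * weight
    loss = float((diff * (pred - target)).sum() / wsum)
    grad = (2.0 / wsum) * diff
    return loss, grad.astype(pred.dtype)


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p["w"]) for p in params]
        self.v = [np.zeros_like(p["w"]) for p in params]
        self.t = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["g"]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p["w"] -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def numerical_gradient(f, w: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar ``f()`` w.r.t. array ``w`` (test helper)."""
    g = np.zeros_like(w, dtype=np.float64)
    it = np.nditer(w, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = w[idx]
        w[idx] = orig + eps
        fp = f()
        w[idx] = orig - eps
        fm = f()
        w[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
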