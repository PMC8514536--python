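"""Minimal numpy implementation of the small fully-convolutional network.

Implements exactly what the training and saliency modules need: 3x3
stride-2 convolutions (im2col + BLAS matmul, float32), ReLU, global average
pooling, a single output unit, Adam, MSE and binary-cross-entropy-with-logits
losses, and backpropagation all the way to the input pixels (for gradient
saliency). Layout is NHWC throughout.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, fan_in: int, shape, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D:
    """3x3 convolution with stride 2 and pad 1 (halves spatial size, ceil)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, ksize: int = 3, stride: int = 2,
                 dtype=np.float32):
        self.cin, self.cout, self.k, self.s = cin, cout, ksize, stride
        self.dtype = dtype
        self.W = _he_init(rng, cin * ksize * ksize, (ksize * ksize * cin, cout), dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        n, _, _, c = xp.shape
        k, s = self.k, self.s
        cols = np.empty((n, oh, ow, k, k, c), dtype=self.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i : i + s * oh : s, j : j + s * ow : s, :]
        return cols.reshape(n * oh * ow, k * k * c)

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        k, s = self.k, self.s
        pad = (k - 1) // 2
        oh = (h + 2 * pad - k) // s + 1
        ow = (w + 2 * pad - k) // s + 1
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        cols = self._im2col(xp, oh, ow)
        y = (cols @ self.W + self.b).reshape(n, oh, ow, self.cout)
        if keep_cache:
            self._cache = (cols, (n, h, w, c), (oh, ow))
        return y

    def backward(self, dy: np.ndarray):
        cols, (n, h, w, c), (oh, ow) = self._cache
        k, s = self.k, self.s
        pad = (k - 1) // 2
        dy2 = dy.reshape(-1, self.cout)
        dW = cols.T @ dy2
        db = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(n, oh, ow, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=self.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += dcols[:, :, :, i, j, :]
        dx = dxp[:, pad : pad + h, pad : pad + w, :]
        self._cache = None
        return dx, [dW, db]


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if keep_cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray):
        dx = dy * self._mask
        self._mask = None
        return dx, []


class GlobalAveragePool:
    def __init__(self):
        self._shape = None

    params: list = []

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if keep_cache:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray):
        n, h, w, c = self._shape
        dx = np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(dy.dtype)
        self._shape = None
        return dx.copy(), []


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.W = _he_init(rng, cin, (cin, cout), dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if keep_cache:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray):
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx, [dW, db]


class SmallCNN:
    """4 stride-2 conv blocks (widths 16/32/64/128) -> GAP -> 1 output unit.

    Fully convolutional: accepts any square input of at least 32 px. The
    output is a raw scalar per image (a logit for classification, a value
    for regression); the sigmoid lives in the loss / predict step.
    """

    MIN_INPUT = 32

    def __init__(self, in_channels: int = 3, widths=(16, 32, 64, 128), seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.dtype = dtype
        self.layers = []
        cin = in_channels
        for wdt in widths:
            self.layers.append(Conv2D(cin, wdt, rng, dtype=dtype))
            self.layers.append(ReLU())
            cin = wdt
        self.layers.append(GlobalAveragePool())
        self.layers.append(Dense(cin, 1, rng, dtype=dtype))

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError("expected a batch of NHWC images")
        if x.shape[1] < self.MIN_INPUT or x.shape[2] < self.MIN_INPUT:
            raise ValueError(f"input must be at least {self.MIN_INPUT} px on each side")
        for layer in self.layers:
            x = layer.forward(x, keep_cache=keep_cache)
        return x[:, 0]

    def backward(self, dout: np.ndarray):
        """Backprop from d(loss)/d(output); returns (d_input, grads per layer)."""
        dy = np.asarray(dout, dtype=self.dtype)[:, None]
        grads: list[list[np.ndarray]] = []
        d = dy
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads.append(g)
        grads.reverse()
        return d, grads

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the scalar output w.r.t. input pixels, per image."""
        out = self.forward(x, keep_cache=True)
        d_input, _ = self.backward(np.ones_like(out))
        return d_input

    # --- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("state does not match architecture")
        for p, s in zip(params, state):
            p[...] = s

    def apply_grads(self, grads: list[list[np.ndarray]], optimizer: "Adam") -> None:
        flat = []
        for g in grads:
            flat.extend(g)
        optimizer.step(self.params, flat)


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * correction * m / (np.sqrt(v) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def mse_loss(outputs: np.ndarray, targets: np.ndarray):
    diff = outputs - targets
    loss = float(np.mean(diff**2))
    dout = (2.0 / len(outputs)) * diff
    return loss, dout


def bce_with_logits_loss(logits: np.ndarray, targets: np.ndarray):
    # softplus(z) - y*z is the numerically stable form of the cross-entropy
    loss = float(np.mean(np.logaddexp(0.0, logits) - targets * logits))
    dout = (sigmoid(logits) - targets) / len(logits)
    return loss, dout
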