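"""Minimal CPU neural-network primitives (numpy, NCHW layout).

Implements exactly what the segmentation network needs: 3x3 convolutions
preceded by reflection padding (so feature maps never shrink), batch
normalisation, leaky ReLU, 2x2 max-pooling, nearest-neighbour upsampling,
and an Adam optimiser. Each layer exposes ``forward(x, train)`` /
``backward(dy)``; parameters and their gradients live on the layer as
``params`` / ``grads`` dictionaries keyed the same way.

The backward passes are exact adjoints of the forwards (verified against
finite differences in the test suite), including the reflection-padding
scatter-add.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def state(self) -> dict:
        """Serializable buffers beyond params (e.g. running statistics)."""
        return {}

    def load_state(self, state: dict) -> None:
        pass


def _reflect_indices(n: int, pad: int) -> np.ndarray:
    """Index map realising symmetric-about-edge ('reflect') padding."""
    idx = np.arange(-pad, n + pad)
    period = max(2 * n - 2, 1)
    idx = np.abs(idx) % period
    idx = np.where(idx >= n, period - idx, idx)
    return idx


class ReflectPad2d(Layer):
    def __init__(self, pad: int):
        super().__init__()
        self.pad = pad
        self._shape = None

    def forward(self, x, train=False):
        p = self.pad
        if p == 0:
            return x
        self._shape = x.shape
        ir = _reflect_indices(x.shape[2], p)
        ic = _reflect_indices(x.shape[3], p)
        self._ir, self._ic = ir, ic
        return x[:, :, ir][:, :, :, ic]

    def backward(self, dy):
        p = self.pad
        if p == 0:
            return dy
        n, c, h, w = self._shape
        # separable scatter-add along rows then columns
        tmp = np.zeros((n, c, h, dy.shape[3]), dtype=dy.dtype)
        np.add.at(tmp, (slice(None), slice(None), self._ir), dy)
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        np.add.at(dx.transpose(0, 1, 3, 2), (slice(None), slice(None), self._ic), tmp.transpose(0, 1, 3, 2))
        return dx


class Conv2d(Layer):
    """k x k convolution with reflection padding, stride 1, same output size."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialisation (leaky-ReLU nets)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": rng.normal(0, scale, (c_out, c_in * k * k)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.pad = ReflectPad2d(k // 2)

    def _im2col(self, xp):
        # xp: (N, C, H+2p, W+2p) -> (N*H*W, C*k*k)
        k = self.k
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        return cols, (n, h, w)

    def forward(self, x, train=False):
        xp = self.pad.forward(x)
        cols, (n, h, w) = self._im2col(xp)
        if train:
            self._cols = cols
            self._nhw = (n, h, w)
            self._xp_shape = xp.shape
        y = cols @ self.params["W"].T + self.params["b"]
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, h, w = self._nhw
        k = self.k
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"][...] = dyf.T @ self._cols
        self.grads["b"][...] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"]).reshape(n, h, w, self.c_in, k, k)
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return self.pad.backward(dxp)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"][...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.running_mean = state["running_mean"].astype(np.float32)
        self.running_var = state["running_var"].astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        if train:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.slope * dy, dy)


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            hit = (xr == y[:, :, :, None, :, None]).transpose(0, 1, 2, 4, 3, 5)
            flat = hit.reshape(n, c, h // 2, w // 2, 4)
            # break double-max ties: route gradient to the first max only
            first = flat & (np.cumsum(flat, axis=-1) == 1)
            self._mask = first.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return y

    def backward(self, dy):
        dx = self._mask * dy[:, :, :, None, :, None]
        n, c, hh, _, ww, _ = dx.shape
        return dx.reshape(n, c, hh * 2, ww * 2)


class UpsampleNearest2x(Layer):
    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of an NCHW tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. logits given gradient w.r.t. softmax output."""
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - dot)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
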