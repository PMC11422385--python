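"""Layers with explicit forward/backward passes (NCHW, float32)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def state(self) -> dict:
        """Snapshot of all weights (and running stats) for checkpointing."""
        return {"params": [p.data.copy() for p in self.params()]}

    def load_state(self, state: dict) -> None:
        for p, d in zip(self.params(), state["params"]):
            p.data[...] = d


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*OH*OW, C*k*k) patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, OH, OW, k, k) -> (N, OH, OW, C, k, k)
    n, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(
    dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int, oh: int, ow: int
) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), np.float32)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, np.float32)
        cols, (oh, ow) = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.data.reshape(self.cout, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.data
        n = x.shape[0]
        out = out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, oh, ow)
        return out

    def backward(self, dout):
        cols, x_shape, oh, ow = self._cache
        n = x_shape[0]
        d = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
        self.w.grad += (d.T @ cols).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += d.sum(axis=0)
        dcols = d @ self.w.data.reshape(self.cout, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class DepthwiseConv2d(Layer):
    """One k x k filter per channel (groups == channels)."""

    def __init__(
        self,
        channels: int,
        k: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.c, self.k, self.stride = channels, k, stride
        self.pad = k // 2
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / (k * k)), (channels, k, k)))
        self.b = Param(np.zeros(channels))
        self._cache = None

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]  # (N, C, OH, OW, k, k)
        out = np.einsum("nchwij,cij->nchw", win, self.w.data, optimize=True)
        out += self.b.data[None, :, None, None]
        if train:
            self._cache = (win, x.shape)
        return out.astype(np.float32)

    def backward(self, dout):
        win, x_shape = self._cache
        self.w.grad += np.einsum("nchw,nchwij->cij", dout, win, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        n, c, h, w = x_shape
        oh, ow = dout.shape[2:]
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[
                    :,
                    :,
                    i : i + self.stride * oh : self.stride,
                    j : j + self.stride * ow : self.stride,
                ] += dout * self.w.data[None, :, i, j, None, None]
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp

    def params(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = (
            self.gamma.data[None, :, None, None] * xhat
            + self.beta.data[None, :, None, None]
        )
        if train:
            self._cache = (xhat, inv, x.shape)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dout * g
        dx = (
            inv[None, :, None, None]
            / n_eff
            * (
                n_eff * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        super().load_state(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        if train:
            self._out = out
        return out.astype(np.float32)

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Swish(Layer):
    """x * sigmoid(x)."""

    def forward(self, x, train=True):
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        if train:
            self._x, self._s = x, s
        return (x * s).astype(np.float32)

    def backward(self, dout):
        s = self._s
        return dout * (s + self._x * s * (1.0 - s))


class MaxPool2d(Layer):
    """2x2, stride 2 (spatial dims must be even)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            # distribute over ties evenly to keep the backward well-defined
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = dout[:, :, :, None, :, None] * self._mask
        return d.reshape(n, c, h, w)


class UpsampleNearest2x(Layer):
    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin)))
        self.b = Param(np.zeros(cout))

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state(self):
        return {"layers": [layer.state() for layer in self.layers]}

    def load_state(self, state):
        for layer, s in zip(self.layers, state["layers"]):
            layer.load_state(s)
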