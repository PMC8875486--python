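"""Minimal NumPy neural-network engine backing the classifier module.

Plain-NumPy layers (im2col convolutions, batch normalization, pooling,
dense), SGD with momentum, and softmax cross-entropy — enough to express
the VGG-16 and DenseNet-201 topologies with per-layer freeze flags and to
train the small ``tiny_test`` network at desk scale.  Arrays are NHWC
float32 throughout; all randomness flows through an explicit Generator, so
runs are bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# -- im2col helpers -------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(n,h,w,c) -> (n,oh,ow,kh,kw,c) view-copy of sliding windows."""
    n, h, w, c = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = np.empty((n, oh, ow, kh, kw, c), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = x[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :]
    return cols, oh, ow


def _col2im(cols: np.ndarray, shape: tuple, kh: int, kw: int, stride: int) -> np.ndarray:
    """Scatter-add the window gradients back onto the padded input shape."""
    n, h, w, c = shape
    oh, ow = cols.shape[1], cols.shape[2]
    dx = np.zeros(shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += cols[:, :, :, i, j, :]
    return dx


class Conv2D(Layer):
    """2-D convolution with 'same'-style zero padding and He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, in_ch, out_ch))
        self.W = Param(w, name=f"{name}.W")
        self.b = Param(np.zeros(out_ch), name=f"{name}.b")
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride)
        n = x.shape[0]
        self._cols = cols.reshape(n * oh * ow, -1)
        out = self._cols @ self.W.value.reshape(-1, self.W.value.shape[-1]) + self.b.value
        return out.reshape(n, oh, ow, -1)

    def backward(self, grad):
        n, oh, ow, f = grad.shape
        gflat = grad.reshape(n * oh * ow, f)
        self.W.grad += (self._cols.T @ gflat).reshape(self.W.value.shape)
        self.b.grad += gflat.sum(axis=0)
        dcols = (gflat @ self.W.value.reshape(-1, f).T).reshape(
            n, oh, ow, self.kernel, self.kernel, self._xshape[-1]
        )
        dx = _col2im(dcols, self._xshape, self.kernel, self.kernel, self.stride)
        if self.pad:
            dx = dx[:, self.pad : -self.pad or None, self.pad : -self.pad or None, :]
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2D(Layer):
    def __init__(self, kernel: int = 2, stride: int | None = None, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride or kernel, pad

    def forward(self, x, train):
        if self.pad:
            x = np.pad(
                x,
                ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)),
                constant_values=-np.inf,
            )
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride)
        n, c = x.shape[0], x.shape[-1]
        flat = cols.reshape(n, oh, ow, self.kernel * self.kernel, c)
        self._argmax = flat.argmax(axis=3)
        return np.take_along_axis(flat, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, oh, ow, c = grad.shape
        flat = np.zeros((n, oh, ow, self.kernel * self.kernel, c), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        cols = flat.reshape(n, oh, ow, self.kernel, self.kernel, c)
        dx = _col2im(cols, self._xshape, self.kernel, self.kernel, self.stride)
        if self.pad:
            dx = dx[:, self.pad : -self.pad or None, self.pad : -self.pad or None, :]
        return dx


class AvgPool2D(Layer):
    """Non-overlapping average pooling; requires divisible spatial dims."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, train):
        n, h, w, c = x.shape
        k = self.kernel
        if h % k or w % k:
            raise ValueError(f"AvgPool2D({k}) needs divisible spatial dims, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))

    def backward(self, grad):
        n, h, w, c = self._shape
        k = self.kernel
        g = grad[:, :, None, :, None, :] / (k * k)
        return np.broadcast_to(g, (n, h // k, k, w // k, k, c)).reshape(n, h, w, c).astype(np.float32)


class BatchNorm(Layer):
    """Per-channel batch normalization (NHWC) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = ""):
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        m = self._m
        dxhat_sum = g.sum(axis=axes)
        dxhat_dot = (g * self._xhat).sum(axis=axes)
        return (self._inv_std / m) * (m * g - dxhat_sum - self._xhat * dxhat_dot)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Downsample(Layer):
    """Fixed block-mean downsampling (a parameter-free stem for tiny_test)."""

    def __init__(self, block: int):
        self._pool = AvgPool2D(block)

    def forward(self, x, train):
        return self._pool.forward(x, train)

    def backward(self, grad):
        return self._pool.backward(grad)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.W = Param(w, name=f"{name}.W")
        self.b = Param(np.zeros(out_dim), name=f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def conv_layers(self) -> list[Conv2D]:
        """All Conv2D layers in definition order, recursing into composites."""
        found: list[Conv2D] = []
        for l in self.layers:
            if isinstance(l, Conv2D):
                found.append(l)
            elif isinstance(l, Sequential):
                found.extend(l.conv_layers())
            elif isinstance(l, DenseBlock):
                for unit in l.units:
                    found.extend(unit.conv_layers())
        return found


class DenseBlock(Layer):
    """Densely connected block: every unit sees the concat of all earlier features."""

    def __init__(self, units: Sequence[Sequential]):
        self.units = list(units)

    def params(self):
        return [p for u in self.units for p in u.params()]

    def forward(self, x, train):
        feats = [x]
        for u in self.units:
            feats.append(u.forward(np.concatenate(feats, axis=-1), train))
        self._widths = [f.shape[-1] for f in feats]
        return np.concatenate(feats, axis=-1)

    def backward(self, grad):
        # Split the output gradient into one slot per stored feature map.
        bounds = np.cumsum(self._widths)[:-1]
        gfeats = [np.ascontiguousarray(g) for g in np.split(grad, bounds, axis=-1)]
        for i in range(len(self.units) - 1, -1, -1):
            gin = self.units[i].backward(gfeats[i + 1])
            inner = np.split(gin, np.cumsum(self._widths[: i + 1])[:-1], axis=-1)
            for j, g in enumerate(inner):
                gfeats[j] = gfeats[j] + g
        return gfeats[0]


# -- loss and optimizer ---------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    return loss, (probs - onehot) / n


class SGDMomentum:
    """Classical SGD with momentum; frozen parameters are never touched."""

    def __init__(self, params: Sequence[Param], lr: float, momentum: float = 0.9):
        self.params = [p for p in params if p.trainable]
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self, all_params: Sequence[Param]) -> None:
        for p in all_params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


# -- checkpointing --------------------------------------------------------

def save_params(model: Sequential, path: str | Path, meta: dict | None = None) -> None:
    """Save all parameters (and running BN stats) to an .npz checkpoint."""
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    for i, l in enumerate(_all_layers(model)):
        if isinstance(l, BatchNorm):
            arrays[f"bn_{i}_mean"] = l.running_mean
            arrays[f"bn_{i}_var"] = l.running_var
    arrays["meta"] = np.frombuffer(json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(model: Sequential, path: str | Path) -> dict:
    """Load a checkpoint saved by :func:`save_params` into a matching model."""
    data = np.load(path)
    for i, p in enumerate(model.params()):
        stored = data[f"param_{i}"]
        if stored.shape != p.value.shape:
            raise ValueError(f"checkpoint shape mismatch for parameter {i}")
        p.value = stored.astype(np.float32)
    for i, l in enumerate(_all_layers(model)):
        if isinstance(l, BatchNorm):
            l.running_mean = data[f"bn_{i}_mean"].astype(np.float32)
            l.running_var = data[f"bn_{i}_var"].astype(np.float32)
    return json.loads(bytes(data["meta"]).decode()) if "meta" in data else {}


def _all_layers(layer: Layer) -> list[Layer]:
    out = [layer]
    if isinstance(layer, Sequential):
        for l in layer.layers:
            out.extend(_all_layers(l))
    elif isinstance(layer, DenseBlock):
        for u in layer.units:
            out.extend(_all_layers(u))
    return out
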