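"""Minimal feed-forward / convolutional layer library with manual gradients.

All layers operate on NHWC float64 arrays (or (N, d) matrices for dense
layers), expose ``forward(x, train)`` / ``backward(dout)``, and accumulate
parameter gradients in ``grads`` keyed like ``params``.  The library is
deliberately small: just enough to express a conv-batchnorm-ReLU-pool image
encoder, a fully connected clinical branch, fusion layers and task heads,
trained with Adam, weight decay and global gradient-norm clipping on a single
CPU thread.  Everything is deterministic given the seeds handed to the
initializers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv2D",
    "BatchNorm2D",
    "MaxPool2D",
    "Flatten",
    "Sequential",
    "Adam",
    "global_norm",
    "clip_by_global_norm",
]


class Layer:
    """Base class: stateless unless it declares ``params``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    """Affine layer y = x W + b for (N, d_in) inputs."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (d_in, d_out), d_in),
            "b": np.zeros(d_out),
        }
        self.zero_grad()
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, kh*kw*C) patches at stride 1 with zero padding."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # stride tricks view over sliding windows
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, h, w, kh, kw, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
        writeable=False,
    )
    return win.reshape(n * h * w, kh * kw * c)


class Conv2D(Layer):
    """Same-padded stride-1 convolution over NHWC inputs."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("odd kernel sizes only")
        rng = rng or np.random.default_rng(0)
        self.ksize = ksize
        self.c_in, self.c_out = c_in, c_out
        fan_in = ksize * ksize * c_in
        self.params = {
            "W": _he_init(rng, (fan_in, c_out), fan_in),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        self._shape = (n, h, w, c)
        pad = self.ksize // 2
        self._cols = _im2col(x, self.ksize, self.ksize, pad)
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, c = self._shape
        k, pad = self.ksize, self.ksize // 2
        dflat = dout.reshape(n * h * w, self.c_out)
        self.grads["W"] += self._cols.T @ dflat
        self.grads["b"] += dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
        # scatter-add patch gradients back (col2im)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad:pad + h, pad:pad + w, :]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N,H,W,C); running stats at eval."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.zero_grad()
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes, m = self._axes, self._m
        self.grads["gamma"] += (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        if not self._train:
            return dxhat / self._std
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling (even spatial dims required)."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {s}")
        xr = x.reshape(n, h // s, s, w // s, s, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        s = self.size
        dr = self._mask * dout[:, :, None, :, None, :]
        # split ties evenly so the gradient is conserved
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        return (dr / counts).reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self, prefix: str = ""):
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_params(f"{prefix}{i}."))
            else:
                for k in layer.params:
                    out[f"{prefix}{i}.{k}"] = (layer, k)
        return out


def global_norm(grads: list[np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))


def clip_by_global_norm(grads: list[np.ndarray], clip: float) -> float:
    """Scale gradients in place so the global L2 norm is at most ``clip``.

    Returns the pre-clipping norm.
    """
    norm = global_norm(grads)
    if clip > 0 and norm > clip:
        scale = clip / norm
        for g in grads:
            g *= scale
    return norm


class Adam:
    """Adam with decoupled weight decay and optional global-norm clipping.

    ``plain_gradient=True`` disables moments entirely (theta <- theta - lr*g),
    the update rule used by the feedback mechanism and the one-step tests.
    """

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0, clip_norm: float = 0.0,
                 plain_gradient: bool = False):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.plain_gradient = plain_gradient
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr: float | None = None) -> float:
        """Apply one update in place; returns the pre-clip gradient norm."""
        lr = self.lr if lr is None else lr
        norm = clip_by_global_norm(grads, self.clip_norm)
        self.t += 1
        for idx, (p, g) in enumerate(zip(params, grads)):
            if self.plain_gradient:
                p -= lr * g
                continue
            m = self._m.setdefault(idx, np.zeros_like(p))
            v = self._v.setdefault(idx, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)
        return norm
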