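"""Minimal CNN building blocks in numpy: layers, loss, and Adam.

The classification network is small enough (four 3×3 conv blocks on a
32×32 input) that explicit numpy forward/backward passes train it on a
single CPU core in minutes. Layers follow the standard formulations:
convolution via im2col matrix multiplication, batch normalization with
running statistics, leaky-ReLU, 2×2/2 max pooling with argmax routing,
and a fully connected head. All arithmetic is float32; arrays are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2x2",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "cross_entropy",
    "Adam",
]


def _f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


class Layer:
    """Base class: parameters exposed as a dict for the optimizer/checkpoint."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (running statistics)."""
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3×3 same-padding convolution without bias (batch norm follows)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        fan_in = in_ch * k * k
        self.k = k
        self.w = _f32(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)))
        self.dw = np.zeros_like(self.w)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.dw}

    def forward(self, x, train):
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k) -> cols: (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = _f32(cols)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, f, h, w = dout.shape
        k, p = self.k, self.k // 2
        c = self._xshape[1]
        dflat = _f32(dout.transpose(0, 2, 3, 1).reshape(n * h * w, f))
        self.dw[...] = (dflat.T @ self._cols).reshape(self.w.shape)
        # scatter columns back (col2im), accumulating in NHWC so the slice
        # additions stay contiguous; one transpose at the end
        dcols = (dflat @ self.w.reshape(f, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        self._cols = None
        return _f32(dxp[:, p : p + h, p : p + w, :].transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = np.einsum("nchw,nchw->c", x, x, optimize=True) / (
                x.shape[0] * x.shape[2] * x.shape[3]
            ) - mean * mean
            var = np.maximum(var, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dx = g * (
            dout
            - (self.dbeta / m)[None, :, None, None]
            - xhat * (self.dgamma / m)[None, :, None, None]
        )
        self._cache = None
        return _f32(dx)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = np.float32(slope)
        self._grad: np.ndarray | None = None

    def forward(self, x, train):
        # for 0 < slope < 1, max(x, slope*x) equals the leaky ReLU
        out = np.maximum(x, self.slope * x)
        if train:
            self._grad = np.where(x > 0, np.float32(1.0), self.slope)
        return out

    def backward(self, dout):
        dx = dout * self._grad
        self._grad = None
        return dx


class MaxPool2x2(Layer):
    """2×2 max pooling with stride 2.

    The gradient is routed by comparing each input to the window maximum;
    exact float ties (measure-zero after batch norm) would split the
    gradient across the tied positions, which leaves training unaffected.
    """

    def __init__(self):
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def forward(self, x, train):
        v = x.reshape(x.shape[0], x.shape[1], x.shape[2] // 2, 2, x.shape[3] // 2, 2)
        out = np.maximum(
            np.maximum(v[:, :, :, 0, :, 0], v[:, :, :, 0, :, 1]),
            np.maximum(v[:, :, :, 1, :, 0], v[:, :, :, 1, :, 1]),
        )
        if train:
            self._x = x
            self._out = out
        return out

    def backward(self, dout):
        n, c, h, w = self._x.shape
        v = self._x.reshape(n, c, h // 2, 2, w // 2, 2)
        dx = np.empty((n, c, h // 2, 2, w // 2, 2), dtype=np.float32)
        for a in (0, 1):
            for b in (0, 1):
                np.multiply(v[:, :, :, a, :, b] == self._out, dout,
                            out=dx[:, :, :, a, :, b])
        self._x = self._out = None
        return dx.reshape(n, c, h, w)


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple | None = None

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _f32(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.w
        self._x = None
        return dx


class Sequential:
    """Ordered layer container with flat parameter naming for checkpoints."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, g in layer.grads().items():
                out[f"{i}.{name}"] = g
        return out

    def named_state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, s in layer.state().items():
                out[f"{i}.{name}"] = s
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), _f32(dlogits / n)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] += (1 - self.beta1) * (g - self.m[k])
            self.v[k] += (1 - self.beta2) * (g * g - self.v[k])
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
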