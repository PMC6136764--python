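"""Minimal CNN engine in NumPy.

Implements exactly the pieces the 9-class EMG decoder needs -- 3x3
"same" convolution, batch normalization, ReLU, 2x2/stride-2 max
pooling, a dense softmax head -- together with stochastic gradient
descent with momentum, L2 weight decay, and early stopping on a
validation set.  Forward/backward passes are expressed as im2col matrix
products so the heavy lifting happens in BLAS; everything runs in
float32.

The engine is deliberately small and deterministic: all initialization
and shuffling is driven by an explicit :class:`numpy.random.Generator`,
so a fixed seed reproduces a training run bit-for-bit on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F = np.float32


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches under 1-pixel zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (N, C, H, W, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=F)


class Conv2d:
    """3x3 convolution, stride 1, zero-padded to preserve spatial size."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(F)
        self.b = np.zeros(out_ch, dtype=F)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    decayed = ("w",)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.T + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        n, _, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        dflat = np.ascontiguousarray(dflat, dtype=F)
        dw = dflat.T @ self._cols
        db = dflat.sum(axis=0)
        # grad wrt input = "same" convolution of dout with flipped kernels
        wk = self.w.reshape(self.out_ch, self.in_ch, self.k, self.k)
        wt = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, -1)
        dcols = _im2col(dout, self.k)
        dx = (dcols @ wt.T).reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx), {"w": dw, "b": db}


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=F)
        self.beta = np.zeros(n_ch, dtype=F)
        self.run_mean = np.zeros(n_ch, dtype=F)
        self.run_var = np.ones(n_ch, dtype=F)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    decayed = ()

    @property
    def state(self) -> dict[str, np.ndarray]:
        return {"run_mean": self.run_mean, "run_var": self.run_var}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ax = (0, 2, 3)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mean).astype(F)
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var).astype(F)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return (self.gamma[:, None, None] * xhat + self.beta[:, None, None]).astype(F)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        xhat, inv, shape = self._cache
        self._cache = None
        ax = (0, 2, 3)
        m = shape[0] * shape[2] * shape[3]
        dgamma = (dout * xhat).sum(axis=ax)
        dbeta = dout.sum(axis=ax)
        g = self.gamma[:, None, None] * inv[:, None, None]
        dx = g * (dout
                  - dbeta[:, None, None] / m
                  - xhat * dgamma[:, None, None] / m)
        return dx.astype(F), {"gamma": dgamma, "beta": dbeta}


class ReLU:
    params: dict = {}
    decayed = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict]:
        dx = dout * self._mask
        self._mask = None
        return dx, {}


class MaxPool2x2:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    params: dict = {}
    decayed = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict]:
        n, c, h, w = self._shape
        r = np.zeros((n, c, h // 2, w // 2, 4), dtype=F)
        np.put_along_axis(r, self._idx[..., None], dout[..., None], axis=-1)
        dx = (r.reshape(n, c, h // 2, w // 2, 2, 2)
               .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))
        self._idx = None
        return np.ascontiguousarray(dx), {}


class Flatten:
    params: dict = {}
    decayed = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict]:
        return dout.reshape(self._shape), {}


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(F)
        self.b = np.zeros(n_out, dtype=F)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    decayed = ("w",)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        dw = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx, {"w": dw, "b": db}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


# ---------------------------------------------------------------------------
# network


class Sequential:
    """A feed-forward stack with a softmax cross-entropy head."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(np.asarray(x, dtype=F), train=False))

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: "SGDM") -> float:
        """One minibatch update; returns the batch loss."""
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        dout = probs.copy()
        dout[np.arange(len(y)), y] -= 1.0
        dout /= len(y)
        dout = dout.astype(F)
        grads: list[dict] = []
        for layer in reversed(self.layers):
            dout, g = layer.backward(dout)
            grads.append(g)
        opt.step(self.layers, list(reversed(grads)))
        return loss

    # -- parameter (de)serialization ---------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"l{i}.{k}"] = v.copy()
            for k, v in getattr(layer, "state", {}).items():
                out[f"l{i}.{k}"] = v.copy()
        return out

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                setattr(layer, k, state[f"l{i}.{k}"].copy())
            for k in getattr(layer, "state", {}):
                setattr(layer, k, state[f"l{i}.{k}"].copy())


class SGDM:
    """Stochastic gradient descent with momentum and L2 weight decay.

    Velocity update ``v <- mu*v - lr*(grad + l2*w)``; weight decay is
    applied to convolution/dense weights only, not biases or batch-norm
    scales.
    """

    def __init__(self, lr: float = 1e-3, momentum: float = 0.9, l2: float = 1e-4):
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self._vel: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: list, grads: list[dict]) -> None:
        for i, (layer, g) in enumerate(zip(layers, grads)):
            for k, dv in g.items():
                w = getattr(layer, k)
                decay = self.l2 if k in layer.decayed else 0.0
                key = (i, k)
                v = self._vel.get(key)
                if v is None:
                    v = np.zeros_like(w)
                v = self.momentum * v - self.lr * (dv.astype(F) + decay * w)
                self._vel[key] = v
                setattr(layer, k, (w + v).astype(F))
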