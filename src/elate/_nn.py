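"""Minimal seeded neural-network core (dense layers, Adam, backprop).

Only what the encoder/decoder/classifier architectures need: fully connected
layers, Elu/Tanh/Sigmoid activations, inverted dropout, a per-block softmax
output, and the Adam optimizer.  Everything is float32 numpy; all randomness
(init, dropout masks, shuffling) flows from one ``numpy.random.Generator``
so runs are reproducible bit-for-bit given a seed.

Backprop is implemented layer-by-layer: ``forward(x, train)`` caches what the
matching ``backward(grad)`` needs, and parameters/gradients are exposed as
flat lists for the optimizer.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine map with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0].T


class Elu(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.where(x > 0, x, self.alpha * np.expm1(x)).astype(np.float32)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = self._out
        return grad * np.where(out > 0, 1.0, out + self.alpha).astype(np.float32)


class Tanh(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._out**2)


class Sigmoid(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:  # rate 0 or eval-mode forward
            return grad
        return grad * self._mask


class BlockSoftmax(Layer):
    """Softmax applied independently inside contiguous blocks of the output.

    ``blocks`` is a list of (start, stop) column ranges; columns outside every
    block (there are none in practice) would pass through unchanged.
    """

    def __init__(self, blocks: list[tuple[int, int]]) -> None:
        super().__init__()
        self.blocks = blocks
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x.copy()
        for a, b in self.blocks:
            seg = x[:, a:b]
            seg = seg - seg.max(axis=1, keepdims=True)
            e = np.exp(seg)
            out[:, a:b] = e / e.sum(axis=1, keepdims=True)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = self._out
        gx = grad.copy()
        for a, b in self.blocks:
            s = out[:, a:b]
            g = grad[:, a:b]
            gx[:, a:b] = s * (g - (g * s).sum(axis=1, keepdims=True))
        return gx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.all_params, state, strict=True):
            p[...] = s


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
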