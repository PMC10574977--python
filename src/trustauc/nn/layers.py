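"""Minimal CPU neural-network layers with analytic backpropagation.

Everything is plain float64 numpy. Layers cache whatever the backward pass
needs during ``forward``; ``backward`` consumes the upstream gradient,
accumulates parameter gradients in place and returns the gradient with
respect to the layer input. Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "SGD",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution, stride 1, no padding (valid), square kernel.

    Implemented as a sum over the k*k kernel offsets so the inner work is a
    single einsum per offset; avoids materialising an im2col buffer.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, rng=None):
        rng = np.random.default_rng(0) if rng is None else rng
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch))
        self.ksize = ksize

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        n, c, h, w = x.shape
        k = self.ksize
        ho, wo = h - k + 1, w - k + 1
        if ho <= 0 or wo <= 0:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}")
        out = np.zeros((n, self.w.value.shape[0], ho, wo))
        for di in range(k):
            for dj in range(k):
                out += np.einsum(
                    "ncij,fc->nfij",
                    x[:, :, di : di + ho, dj : dj + wo],
                    self.w.value[:, :, di, dj],
                    optimize=True,
                )
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        x = self._x
        k = self.ksize
        ho, wo = dout.shape[2], dout.shape[3]
        dx = np.zeros_like(x)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        for di in range(k):
            for dj in range(k):
                xs = x[:, :, di : di + ho, dj : dj + wo]
                self.w.grad[:, :, di, dj] += np.einsum(
                    "nfij,ncij->fc", dout, xs, optimize=True
                )
                dx[:, :, di : di + ho, dj : dj + wo] += np.einsum(
                    "nfij,fc->ncij", dout, self.w.value[:, :, di, dj], optimize=True
                )
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd row/column is dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xc = x[:, :, : 2 * hh, : 2 * ww]
        self._in_shape = x.shape
        windows = xc.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = windows.reshape(n, c, hh, ww, 4)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        hh, ww = h // 2, w // 2
        dflat = np.zeros((n, c, hh, ww, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, : 2 * hh, : 2 * ww] = (
            dflat.reshape(n, c, hh, ww, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * hh, 2 * ww)
        )
        return dx


class GlobalAvgPool(Layer):
    """Spatial mean: (n, c, h, w) -> (n, c)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng=None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Sequential(Layer):
    """An ordered container of named layers.

    Keeps per-layer outputs from the last forward pass so gradients with
    respect to an intermediate activation (needed for class-activation
    maps) can be obtained with :meth:`backward_until`.
    """

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = list(layers)

    def names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def _index(self, name: str) -> int:
        for i, (n, _) in enumerate(self.layers):
            if n == name:
                return i
        raise KeyError(f"no layer named {name!r}; have {self.names()}")

    def __getitem__(self, name: str) -> Layer:
        return self.layers[self._index(name)][1]

    def params(self):
        out = []
        for _, layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        self._outs = []
        for _, layer in self.layers:
            x = layer.forward(x)
            self._outs.append(x)
        return x

    def backward(self, dout):
        for _, layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def backward_until(self, dout, target: str):
        """Backpropagate from the output down to (exclusive) layer ``target``.

        Returns the gradient with respect to ``target``'s output. Requires a
        preceding forward pass.
        """
        idx = self._index(target)
        for _, layer in reversed(self.layers[idx + 1 :]):
            dout = layer.backward(dout)
        return dout

    def output_of(self, target: str):
        return self._outs[self._index(target)]

    # ---- (de)serialisation -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, layer in self.layers:
            for j, p in enumerate(layer.params()):
                state[f"{name}.{j}"] = p.value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for j, p in enumerate(layer.params()):
                key = f"{name}.{j}"
                if key not in state:
                    raise KeyError(f"missing weight {key}")
                val = np.asarray(state[key], dtype=float)
                if val.shape != p.value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {val.shape} vs {p.value.shape}"
                    )
                p.value = val.copy()
                p.grad = np.zeros_like(p.value)

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._v):
            if not np.all(np.isfinite(p.grad)):
                raise FloatingPointError("non-finite gradient encountered")
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
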