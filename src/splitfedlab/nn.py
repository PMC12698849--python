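"""Minimal feed-forward CNN machinery on numpy.

Every layer caches what its backward pass needs, accumulates parameter
gradients into ``.grads`` and returns the gradient with respect to its input.
This gives the rest of the package exact, per-sample access to parameter
gradients at any split point of the network — the quantity both the training
protocol and the gradient-matching attack are built on.

All arithmetic is float64; parameter arrays are never rebound after
construction (optimizers and parameter vectors write in place), so optimizer
state keyed by position stays valid across federated averaging.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: a differentiable module with named parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def param_names(self) -> list[str]:
        """Parameter names in flattening order: weights before biases."""
        order = {"weight": 0, "bias": 1}
        return sorted(self.params, key=lambda n: (order.get(n, 99), n))

    def zero_grad(self) -> None:
        for name, p in self.params.items():
            self.grads[name] = np.zeros_like(p)


class Conv2d(Layer):
    """2-D convolution (stride 1) via an im2col matrix product.

    Input/output layout is (N, C, H, W). ``padding`` is symmetric zero
    padding; with kernel 3 and padding 1 spatial size is preserved.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: int = 1) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.params["weight"] = np.zeros(
            (out_channels, in_channels, kernel_size, kernel_size))
        self.params["bias"] = np.zeros(out_channels)
        self.zero_grad()

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * self.kernel_size ** 2
        self.params["weight"][...] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), self.params["weight"].shape)
        self.params["bias"][...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k, p = self.kernel_size, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.params["bias"]
        self._cols = cols
        self._in_shape = (n, c, h, w)
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k, p = self.kernel_size, self.padding
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.grads["weight"] += (dyf.T @ self._cols).reshape(
            self.params["weight"].shape)
        self.grads["bias"] += dyf.sum(axis=0)
        dcols = (dyf @ self.params["weight"].reshape(self.out_channels, -1))
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j]
        if p:
            return dxp[:, :, p:p + h, p:p + w]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Layer):
    """Non-overlapping max pooling; spatial dims must divide the pool size.

    Ties within a window route the gradient to the first maximal element,
    a deterministic subgradient choice.
    """

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool {s}")
        xr = (x.reshape(n, c, h // s, s, w // s, s)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, h // s, w // s, s * s))
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = (n, c, h, w)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        s = self.size
        dxr = np.zeros((n, c, h // s, w // s, s * s))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        return (dxr.reshape(n, c, h // s, w // s, s, s)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h, w))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params["weight"] = np.zeros((in_features, out_features))
        self.params["bias"] = np.zeros(out_features)
        self.zero_grad()

    def init_params(self, rng: np.random.Generator) -> None:
        self.params["weight"][...] = rng.normal(
            0.0, np.sqrt(2.0 / self.in_features), self.params["weight"].shape)
        self.params["bias"][...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ValueError(
                f"expected (n, {self.in_features}) input, got {x.shape}")
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["weight"] += self._x.T @ dy
        self.grads["bias"] += dy.sum(axis=0)
        return dy @ self.params["weight"].T


class Sequential:
    """An ordered stack of layers; an empty stack is the identity map."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self) -> list[tuple[str, np.ndarray]]:
        """Stable flattening order: layer order, weights before biases."""
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.param_names():
                out.append((f"{i}.{type(layer).__name__.lower()}.{name}",
                            layer.params[name]))
        return out

    def named_grads(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.param_names():
                out.append((f"{i}.{type(layer).__name__.lower()}.{name}",
                            layer.grads[name]))
        return out

    def param_arrays(self) -> list[np.ndarray]:
        return [a for _, a in self.named_params()]

    def grad_arrays(self) -> list[np.ndarray]:
        return [a for _, a in self.named_grads()]

    def n_params(self) -> int:
        return int(sum(a.size for a in self.param_arrays()))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    Returns ``(loss, dlogits)`` with ``dlogits = (softmax - onehot) / n``.
    """
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {n}")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= c:
        raise ValueError(f"labels out of range for {c} classes")
    p = softmax(logits)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-300).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class SGD:
    """Plain gradient descent, matching the update rule the protocol equations
    are written in."""

    def __init__(self, arrays: list[np.ndarray], lr: float) -> None:
        self.arrays = arrays
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.arrays, grads, strict=True):
            p -= self.lr * g


class Adam:
    """Adam with optional AMSGrad; state is positional, so in-place parameter
    rewrites (federated averaging) keep it attached."""

    def __init__(self, arrays: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 amsgrad: bool = True) -> None:
        self.arrays = arrays
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.vhat = [np.zeros_like(a) for a in arrays] if amsgrad else None

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(self.arrays, grads, strict=True)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                denom = np.sqrt(self.vhat[i] / bc2) + self.eps
            else:
                denom = np.sqrt(self.v[i] / bc2) + self.eps
            p -= self.lr * mhat / denom


def make_optimizer(name: str, arrays: list[np.ndarray], lr: float,
                   amsgrad: bool = True):
    if name == "sgd":
        return SGD(arrays, lr)
    if name == "adam":
        return Adam(arrays, lr, amsgrad=amsgrad)
    raise ValueError(f"unknown optimizer {name!r}")
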