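"""Minimal feed-forward neural-network layers with hand-written backprop.

Everything is plain NumPy: no framework dependency, fully deterministic
given a seeded ``numpy.random.Generator``. Layers expose ``forward`` /
``backward`` and hold their parameters and gradients in dicts so an
optimizer can iterate over them generically.

Shapes follow the (batch, features) convention throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNormCenter",
    "ReLU",
    "Dropout",
    "Sequential",
    "Adam",
]

_BN_EPS = 1e-3  # matches the common framework default for batch norm


class Layer:
    """Base class; stateless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map ``x @ W + b`` with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class BatchNormCenter(Layer):
    """Batch normalization with a learnable offset but no learnable scale.

    Activations are standardized by batch statistics in training mode and
    by exponential running statistics (momentum 0.99) in evaluation mode;
    only a per-feature offset ``beta`` is learned.
    """

    def __init__(self, n_features: int, momentum: float = 0.99) -> None:
        super().__init__()
        self.params = {"beta": np.zeros(n_features)}
        self.grads = {"beta": np.zeros(n_features)}
        self.momentum = momentum
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._cache: tuple | None = None

    def forward(self, x, training, rng=None):
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch normalization requires batch_size >= 2 in training mode")
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xc = x - mean
            xhat = xc * inv_std
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            self._cache = (xc, inv_std, xhat)
            return xhat + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + _BN_EPS)
        return xhat + self.params["beta"]

    def backward(self, grad):
        xc, inv_std, xhat = self._cache
        m = xc.shape[0]
        self.grads["beta"] = grad.sum(axis=0)
        # gamma == 1 batch-norm backward
        dxhat = grad
        dvar = np.sum(dxhat * xc, axis=0) * (-0.5) * inv_std**3
        dmean = -inv_std * dxhat.sum(axis=0) + dvar * (-2.0 / m) * xc.sum(axis=0)
        return dxhat * inv_std + dvar * (2.0 / m) * xc + dmean / m


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode or at rate 0."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential:
    """A forward/backward chain of layers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


def mlp_stack(
    widths: tuple[int, ...],
    dropout_rate: float,
    rng: np.random.Generator,
) -> list[Layer]:
    """Hidden-layer recipe: affine -> center-only batch norm -> ReLU -> dropout.

    ``widths`` lists consecutive layer sizes; the returned stack maps
    ``widths[0]`` to ``widths[-1]`` applying the recipe at every
    intermediate width. No output layer is appended here.
    """
    layers: list[Layer] = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        layers += [
            Dense(n_in, n_out, rng),
            BatchNormCenter(n_out),
            ReLU(),
            Dropout(dropout_rate),
        ]
    return layers


class Adam:
    """Adaptive-moment SGD over the parameters of several Sequentials."""

    def __init__(self, modules, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip_norm: float | None = None):
        self.slots = [(layer, name) for mod in modules for layer, name in mod.parameters()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(l.grads[n] ** 2)) for l, n in self.slots))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for layer, name in self.slots:
                    layer.grads[name] = layer.grads[name] * scale
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
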