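"""Minimal fully-connected neural-network primitives in numpy.

Implements exactly what the feature encoders need — dense layers, batch
normalization, rectifier activations and the Adam optimizer — with
hand-written backward passes. Layers cache their forward inputs, so a
``forward`` must precede each ``backward``; parameter gradients
accumulate in ``grads`` until the optimizer step consumes them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "BatchNorm", "ReLU", "Sequential", "Adam", "softplus", "softplus_grad"]


class Layer:
    params: dict
    grads: dict

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self):
        """Yield (layer, name) handles for every trainable array."""
        for name in self.params:
            yield self, name


class Dense(Layer):
    """Affine map x @ W + b with Kaiming/He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.params = {"gamma": np.ones(n), "beta": np.zeros(n)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache = None

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad):
        xhat, inv_std, train = self._cache
        self.grads["gamma"] += (grad * xhat).sum(axis=0)
        self.grads["beta"] += grad.sum(axis=0)
        dxhat = grad * self.params["gamma"]
        if not train:
            return dxhat * inv_std
        n = grad.shape[0]
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class ReLU(Layer):
    def __init__(self):
        self.params = {}
        self.grads = {}
        self._mask: np.ndarray | None = None

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)
        self.params = {}
        self.grads = {}

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        """Yield (layer, name) pairs for every trainable array."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.parameters()
            else:
                for name in layer.params:
                    yield layer, name


class Adam:
    """Adam optimizer over a collection of (layer, param-name) handles."""

    def __init__(self, handles, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.handles = list(handles)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.handles]

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer, name in self.handles:
            layer.grads[name][...] = 0.0


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def softplus_grad(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
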