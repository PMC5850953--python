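"""Minimal NumPy neural-network primitives used by the phylogeny-aware CNN.

Activations, Glorot initialisation and an Adam optimizer; everything is
driven by a single seeded Generator so training runs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

# SELU constants (self-normalising networks)
_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def selu(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0).astype(x.dtype)


def identity(x: np.ndarray) -> np.ndarray:
    return x


def identity_grad(x: np.ndarray) -> np.ndarray:
    return np.ones_like(x)


ACTIVATIONS = {
    "selu": (selu, selu_grad),
    "relu": (relu, relu_grad),
    "linear": (identity, identity_grad),
}


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, learning_rate: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, frozen: set | None = None) -> None:
        self.t += 1
        frozen = frozen or set()
        for k, g in grads.items():
            if k in frozen:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
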