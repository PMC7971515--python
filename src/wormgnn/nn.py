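"""Layers and optimizer for the perceptron building blocks.

Everything here operates on :class:`~wormgnn.autodiff.Tensor`.  The layers
are deliberately minimal: dense layers, a per-batch feature-normalization
layer (used to standardize activations on each worm's data separately), and
Adam.  Parameter initialization is Kaiming-uniform, seeded through a numpy
``Generator`` so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "BatchFeatureNorm", "Perceptron2", "Adam"]


def _kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Dense layer ``x @ W + b`` acting on the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Tensor(_kaiming_uniform(rng, in_dim, (in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchFeatureNorm:
    """Standardize activations using statistics of the current batch.

    Training iterates one individual at a time, so the batch statistics are
    per-worm statistics by construction; at evaluation the caller passes a
    whole recording of one worm, giving the same per-worm behavior without
    running averages.  A learned gain/shift follows the standardization.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        # statistics over all axes except the last (feature) axis
        axes = tuple(range(x.ndim - 1))
        mu = x.mean(axis=axes, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=axes, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Perceptron2:
    """Two-layer perceptron with ReLU, optionally feature-normalized.

    The normalization layer sits after the first dense layer, before the
    nonlinearity.  ``zero_output`` zeroes the second layer so the block
    starts as the constant-zero map — used for residual predictor heads,
    which then begin training at the identity (persistence) map.
    """

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator, feature_norm: bool = False,
                 zero_output: bool = False):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.norm = BatchFeatureNorm(hidden) if feature_norm else None
        self.fc2 = Linear(hidden, out_dim, rng)
        if zero_output:
            self.fc2.W.data[...] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        if self.norm is not None:
            h = self.norm(h)
        return self.fc2(h.relu())

    def parameters(self) -> list[Tensor]:
        params = self.fc1.parameters() + self.fc2.parameters()
        if self.norm is not None:
            params += self.norm.parameters()
        return params


class Adam:
    """Adaptive-moment first-order optimizer."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
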