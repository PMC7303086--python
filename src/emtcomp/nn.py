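"""Minimal fully-connected network with leaky ReLU, dropout and Adam.

Small enough (a few thousand weights) that plain numpy is the right tool:
per-batch work is matmul-bound on matrices of at most a few hundred rows.
Dropout uses the inverted convention so the deterministic forward pass needs
no rescaling; masks can stay active at inference for Monte-Carlo sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def leaky_relu(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, x, alpha * x)


def leaky_relu_grad(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, 1.0, alpha)


@dataclass
class MLP:
    """Feed-forward net; hidden layers share one activation, linear output."""

    layer_sizes: Sequence[int]           # [in, h1, ..., out]
    alpha: float = 0.01                  # leaky-ReLU negative slope
    dropout_rate: float = 0.0            # on hidden activations only
    seed: int = 0
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.weights:
            rng = np.random.default_rng(self.seed)
            for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
                limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
                self.weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
                self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(
        self,
        x: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
        keep_cache: bool = False,
    ):
        """Forward pass; pass ``dropout_rng`` to sample an active dropout mask.

        Returns the output, or ``(output, cache)`` when ``keep_cache`` for a
        subsequent :meth:`backward` call.
        """
        a = np.asarray(x, dtype=float)
        pre, acts, masks = [], [a], []
        rate = self.dropout_rate if dropout_rng is not None else 0.0
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if li < self.n_layers - 1:
                a = leaky_relu(z, self.alpha)
                if rate > 0.0:
                    mask = (dropout_rng.random(a.shape) >= rate) / (1.0 - rate)
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                a = z
            pre.append(z)
            acts.append(a)
        if keep_cache:
            return a, (pre, acts, masks)
        return a

    def backward(self, grad_out: np.ndarray, cache) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of a scalar loss w.r.t. weights/biases, given dL/d(output)."""
        pre, acts, masks = cache
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * self.n_layers
        delta = np.asarray(grad_out, dtype=float)
        for li in range(self.n_layers - 1, -1, -1):
            a_prev = acts[li]
            grads[li] = (a_prev.T @ delta, delta.sum(axis=0))
            if li > 0:
                delta = delta @ self.weights[li].T
                if masks[li - 1] is not None:
                    delta = delta * masks[li - 1]
                delta = delta * leaky_relu_grad(pre[li - 1], self.alpha)
        return grads

    def copy_parameters(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_parameters(self, params: tuple[list[np.ndarray], list[np.ndarray]]) -> None:
        self.weights = [w.copy() for w in params[0]]
        self.biases = [b.copy() for b in params[1]]


class Adam:
    """Adam optimiser over an MLP's weight/bias lists."""

    def __init__(self, net: MLP, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(w), np.zeros_like(b))
                  for w, b in zip(net.weights, net.biases)]
        self.v = [(np.zeros_like(w), np.zeros_like(b))
                  for w, b in zip(net.weights, net.biases)]

    def step(self, grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for li, (gw, gb) in enumerate(grads):
            mw, mb = self.m[li]
            vw, vb = self.v[li]
            mw += (1 - self.beta1) * (gw - mw)
            mb += (1 - self.beta1) * (gb - mb)
            vw += (1 - self.beta2) * (gw**2 - vw)
            vb += (1 - self.beta2) * (gb**2 - vb)
            self.net.weights[li] -= self.lr * (mw / b1c) / (np.sqrt(vw / b2c) + self.eps)
            self.net.biases[li] -= self.lr * (mb / b1c) / (np.sqrt(vb / b2c) + self.eps)
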