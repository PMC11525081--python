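"""Minimal fully connected networks with ReLU activations and Adam.

Two hidden layers of a few hundred units over 40-dimensional inputs are
small enough that plain numpy matrix products train them in seconds, so
the networks (and their backward passes) are written directly here.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Feed-forward network: linear -> ReLU per hidden layer, linear output."""

    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.sizes = tuple(sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to ReLU
            self.weights.append(rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in))
            self.biases.append(np.zeros(n_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_from(self, other: "MLP", rate: float = 1.0) -> None:
        """Polyak update: theta <- rate * theta_other + (1 - rate) * theta."""
        for mine, theirs in zip(self.params, other.params):
            mine *= 1.0 - rate
            mine += rate * theirs

    def forward(self, X: np.ndarray, cache: bool = False):
        acts = [np.asarray(X, dtype=float)]
        h = acts[0]
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
            if cache:
                acts.append(h)
        return (h, acts) if cache else h

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def backward(self, acts: list[np.ndarray], d_out: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. params given cached activations and output grad."""
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = d_out
        for i in range(len(self.weights) - 1, -1, -1):
            if i < len(self.weights) - 1:
                delta = delta * (acts[i + 1] > 0)
            gw[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return gw + gb


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
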