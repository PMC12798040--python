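"""Minimal feed-forward network machinery (dense layers, Adam, dropout).

Small fully-connected stacks trained on CPU; everything is seeded through
``numpy.random.Generator`` so training is bit-reproducible on a fixed
platform.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Fully connected stack: ReLU on hidden layers, linear output.

    ``widths`` is ``[n_in, h1, ..., n_out]``. Inverted dropout with rate
    ``dropout`` is applied to hidden activations during training only.
    """

    def __init__(self, widths: list[int], rng: np.random.Generator, relu_output: bool = False):
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = list(widths)
        self.relu_output = relu_output
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache: list[tuple] = []

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def _is_relu(self, layer: int) -> bool:
        return layer < self.n_layers - 1 or self.relu_output

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.widths[0]:
            raise ValueError(
                f"input width {x.shape[1]} != expected {self.widths[0]}"
            )
        self._cache = []
        h = x
        for layer in range(self.n_layers):
            z = h @ self.weights[layer] + self.biases[layer]
            a = np.maximum(z, 0.0) if self._is_relu(layer) else z
            mask = None
            if train and dropout > 0.0 and layer < self.n_layers - 1:
                if rng is None:
                    raise ValueError("dropout during training requires an rng")
                mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
            self._cache.append((h, z, mask))
            h = a
        return h

    def backward(self, d_out: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Backprop from output gradient; returns (dW, db, dX)."""
        grads_w: list[np.ndarray] = [np.empty(0)] * self.n_layers
        grads_b: list[np.ndarray] = [np.empty(0)] * self.n_layers
        grad = np.asarray(d_out, dtype=float)
        for layer in range(self.n_layers - 1, -1, -1):
            h_in, z, mask = self._cache[layer]
            if mask is not None:
                grad = grad * mask
            if self._is_relu(layer):
                grad = grad * (z > 0.0)
            grads_w[layer] = h_in.T @ grad
            grads_b[layer] = grad.sum(axis=0)
            grad = grad @ self.weights[layer].T
        return grads_w, grads_b, grad

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]


class Adam:
    """Adaptive-moment optimizer over a flat list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
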