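"""Minimal numpy neural-network primitives shared by the autoencoder and CNN.

All training here is plain-CPU, deterministic-given-seed numpy: seeded
initialization, seeded mini-batch shuffling, and Adam updates. The Adam
step works in preallocated buffers because the autoencoder's first layer
can carry millions of parameters and per-step temporaries dominate the
runtime otherwise.
"""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._buf = [np.empty_like(p) for p in params]
        self._buf2 = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, g, m, v, buf, buf2 in zip(
            self.params, grads, self.m, self.v, self._buf, self._buf2
        ):
            m *= b1
            m += (1 - b1) * g
            np.multiply(g, g, out=buf)
            v *= b2
            buf *= 1 - b2
            v += buf
            # update = lr * (m/c1) / (sqrt(v/c2) + eps)
            np.divide(v, c2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf2)
            buf2 *= self.lr / c1
            p -= buf2


def he_init(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    return rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)


def dense_relu_forward(
    X: np.ndarray, layers: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward X through affine+ReLU layers.

    Returns the final output and the per-layer activation list
    ``[X, h1, ..., out]`` needed for backprop.
    """
    acts = [X]
    H = X
    for W, b in layers:
        if H.shape[1] != W.shape[0]:
            raise ValueError(f"layer expects {W.shape[0]} inputs, got {H.shape[1]}")
        H = np.maximum(H @ W + b, 0.0)
        acts.append(H)
    return H, acts


def dense_relu_backward(
    d_out: np.ndarray,
    acts: list[np.ndarray],
    layers: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Backprop through the chain given cached activations.

    Returns ``(d_input, grads)`` with grads ordered [dW0, db0, dW1, db1, ...].
    """
    grads: list[np.ndarray] = []
    d = d_out
    for idx in range(len(layers) - 1, -1, -1):
        W, _b = layers[idx]
        d = d * (acts[idx + 1] > 0)
        grads.insert(0, acts[idx].T @ d)
        grads.insert(1, d.sum(axis=0))
        d = d @ W.T
    return d, grads
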