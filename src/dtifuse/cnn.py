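"""1-D convolutional classifier over drug-protein pair vectors.

A pair is represented by concatenating the fused drug descriptor and the
fused protein descriptor into one 1-D signal. The network is

    conv (N_k kernels, valid, stride 1) -> ReLU -> max-pool -> flatten
    -> fully connected -> softmax over {no interaction, interaction}

trained with cross-entropy by mini-batch Adam. Everything is plain numpy
with hand-written backprop, so training and scoring are deterministic given
the seed, and the gradient can be checked against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import Adam
from .features import FeatureMatrix


@dataclass
class LabeledPairSet:
    """(drug index, protein index) pairs with binary labels."""

    pairs: list[tuple[int, int]]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.pairs) != self.labels.shape[0]:
            raise ValueError("pairs and labels length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def validate_against(self, network) -> None:
        """Check positives are known DTIs and negatives are unknown pairs."""
        for (i, j), y in zip(self.pairs, self.labels):
            if y == 1 and network.A[i, j] != 1:
                raise ValueError(f"positive pair {(i, j)} is not a known DTI")
            if y == 0 and network.A[i, j] != 0:
                raise ValueError(f"negative pair {(i, j)} is a known DTI")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ConvNetModel:
    """Trained CNN parameters plus the input standardization statistics."""

    kernels: np.ndarray  # (n_kernels, kernel_len)
    kernel_bias: np.ndarray  # (n_kernels,)
    dense_W: np.ndarray  # (flattened dim, 2)
    dense_b: np.ndarray  # (2,)
    pool_size: int
    input_len: int
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    training_trace: list[float] = field(default_factory=list)
    seed: int = 0

    def save(self, path: str | Path) -> None:
        """Checkpoint as JSON text (floats round-trip exactly via repr)."""
        payload = {
            "kernels": self.kernels.tolist(),
            "kernel_bias": self.kernel_bias.tolist(),
            "dense_W": self.dense_W.tolist(),
            "dense_b": self.dense_b.tolist(),
            "pool_size": self.pool_size,
            "input_len": self.input_len,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "training_trace": self.training_trace,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ConvNetModel":
        z = json.loads(Path(path).read_text())
        return cls(
            kernels=np.array(z["kernels"]),
            kernel_bias=np.array(z["kernel_bias"]),
            dense_W=np.array(z["dense_W"]),
            dense_b=np.array(z["dense_b"]),
            pool_size=int(z["pool_size"]),
            input_len=int(z["input_len"]),
            feature_mean=np.array(z["feature_mean"]),
            feature_scale=np.array(z["feature_scale"]),
            training_trace=list(z["training_trace"]),
            seed=int(z["seed"]),
        )


def conv1d_forward(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Valid stride-1 1-D convolution (cross-correlation) of x with one kernel.

    Output[m] = sum_i kernel[i] * x[m + i] + bias for m = 0 .. L - N_w.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape[0] > x.shape[0]:
        raise ValueError(
            f"kernel length {kernel.shape[0]} exceeds input length {x.shape[0]}"
        )
    return np.correlate(x, kernel, mode="valid") + bias


def relu(v: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(v, dtype=float), 0.0)


def maxpool(v: np.ndarray, pool_size: int) -> np.ndarray:
    """Max over non-overlapping windows; a trailing partial window is pooled as-is."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("cannot pool an empty vector")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return np.maximum.reduceat(v, np.arange(0, v.size, pool_size))


def softmax_head(h: np.ndarray) -> np.ndarray:
    """Exp-normalized probabilities for a 2-logit head (shift-by-max stable)."""
    h = np.asarray(h, dtype=float)
    shifted = h - h.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _pooled_len(m: int, pool: int) -> int:
    return -(-m // pool)


def _forward_batch(X: np.ndarray, model: ConvNetModel):
    """Vectorized forward pass; returns probs and the caches backprop needs."""
    W = model.kernels.shape[1]
    windows = np.ascontiguousarray(sliding_window_view(X, W, axis=1))
    B, M, _ = windows.shape
    C = (windows.reshape(B * M, W) @ model.kernels.T).reshape(B, M, -1)
    C = np.ascontiguousarray(C.transpose(0, 2, 1)) + model.kernel_bias[None, :, None]
    R = np.maximum(C, 0.0)
    B, K, M = R.shape
    p = model.pool_size
    n_pools = _pooled_len(M, p)
    pad = n_pools * p - M
    Rp = np.pad(R, ((0, 0), (0, 0), (0, pad)), constant_values=-np.inf)
    Rp = Rp.reshape(B, K, n_pools, p)
    arg = Rp.argmax(axis=3)
    pooled = np.take_along_axis(Rp, arg[..., None], axis=3)[..., 0]
    flat = pooled.reshape(B, K * n_pools)
    logits = flat @ model.dense_W + model.dense_b
    probs = softmax_head(logits)
    return probs, (windows, C, arg, flat, pad)


def _loss_and_grads(
    model: ConvNetModel, xb: np.ndarray, yb: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Mean cross-entropy on a batch and its gradients w.r.t. all parameters.

    Gradient order matches the parameter list
    [kernels, kernel_bias, dense_W, dense_b].
    """
    probs, (windows, C, arg, flat, pad) = _forward_batch(xb, model)
    B = xb.shape[0]
    loss = -float(np.mean(np.log(probs[np.arange(B), yb] + 1e-12)))
    d_logits = probs.copy()
    d_logits[np.arange(B), yb] -= 1.0
    d_logits /= B
    g_dense_W = flat.T @ d_logits
    g_dense_b = d_logits.sum(axis=0)
    d_flat = d_logits @ model.dense_W.T
    Kk, p = model.kernels.shape[0], model.pool_size
    n_pools = d_flat.shape[1] // Kk
    d_pool = d_flat.reshape(B, Kk, n_pools)
    M = C.shape[2]
    dRp = np.zeros((B, Kk, n_pools, p))
    np.put_along_axis(dRp, arg[..., None], d_pool[..., None], axis=3)
    dR = dRp.reshape(B, Kk, n_pools * p)[:, :, :M]
    dC = dR * (C > 0)
    Wl = windows.shape[2]
    dCm = dC.transpose(0, 2, 1).reshape(B * M, Kk)
    g_kernels = dCm.T @ windows.reshape(B * M, Wl)
    g_kbias = dC.sum(axis=(0, 2))
    return loss, [g_kernels, g_kbias, g_dense_W, g_dense_b]


def pair_matrix(
    pairs: Sequence[tuple[int, int]],
    fused_drug: FeatureMatrix,
    fused_protein: FeatureMatrix,
) -> np.ndarray:
    """Stack [fused drug row | fused protein row] signals for a pair list."""
    n_d, n_p = fused_drug.X.shape[0], fused_protein.X.shape[0]
    for i, j in pairs:
        if not (0 <= i < n_d and 0 <= j < n_p):
            raise IndexError(f"pair {(i, j)} references an unknown entity")
    di = np.array([i for i, _ in pairs], dtype=int)
    pj = np.array([j for _, j in pairs], dtype=int)
    return np.hstack([fused_drug.X[di], fused_protein.X[pj]])


def train_cnn(
    train_set: LabeledPairSet,
    fused_drug: FeatureMatrix,
    fused_protein: FeatureMatrix,
    hyper,
    seed: int = 0,
) -> ConvNetModel:
    """Train the convolutional pair classifier with cross-entropy + Adam.

    Inputs are standardized per feature using training-set statistics (stored
    in the model and re-applied at scoring time). Raises if the training set
    contains a single class or the loss becomes non-finite.
    """
    if len(train_set) == 0 or len(set(train_set.labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    X = pair_matrix(train_set.pairs, fused_drug, fused_protein)
    y = train_set.labels
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    L = Xs.shape[1]
    W = hyper.cnn_kernel_len
    if W > L:
        raise ValueError(f"kernel length {W} exceeds pair vector length {L}")
    K = hyper.cnn_n_kernels
    rng = np.random.default_rng(seed)
    M = L - W + 1
    n_pools = _pooled_len(M, hyper.cnn_pool_size)
    model = ConvNetModel(
        kernels=rng.standard_normal((K, W)) * np.sqrt(2.0 / W),
        kernel_bias=np.zeros(K),
        dense_W=rng.standard_normal((K * n_pools, 2)) * np.sqrt(2.0 / (K * n_pools)),
        dense_b=np.zeros(2),
        pool_size=hyper.cnn_pool_size,
        input_len=L,
        feature_mean=mean,
        feature_scale=scale,
        seed=seed,
    )
    params = [model.kernels, model.kernel_bias, model.dense_W, model.dense_b]
    opt = Adam(params, lr=hyper.cnn_learning_rate)
    n = Xs.shape[0]
    batch_size = hyper.cnn_batch_size
    for _ in range(hyper.cnn_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = _loss_and_grads(model, Xs[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("CNN training diverged")
            epoch_loss += loss * len(idx)
            opt.step(grads)
        model.training_trace.append(epoch_loss / n)
    return model


def predict_scores(
    model: ConvNetModel,
    pairs: Sequence[tuple[int, int]],
    fused_drug: FeatureMatrix,
    fused_protein: FeatureMatrix,
) -> np.ndarray:
    """Interaction-class probability for each pair (deterministic forward pass)."""
    if len(pairs) == 0:
        return np.zeros(0)
    X = pair_matrix(pairs, fused_drug, fused_protein)
    if X.shape[1] != model.input_len:
        raise ValueError(
            f"pair vector length {X.shape[1]} != model input length {model.input_len}"
        )
    Xs = (X - model.feature_mean) / model.feature_scale
    probs, _ = _forward_batch(Xs, model)
    return probs[:, 1]
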