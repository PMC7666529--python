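"""Compact feature learning: stacked autoencoder compression and fusion.

Each side of the network (drugs, targets) gets one stacked autoencoder (SAE)
trained to reconstruct the concatenated [GIP kernel row | attribute vector]
block through a bottleneck; the bottleneck code is the compact attribute
representation. The fused descriptor of an entity is the concatenation

    [ SAE-encoded(GIP row | attributes)  |  graph-embedding row ]

so it carries interaction-profile similarity, chemistry/sequence attributes,
and network topology at once.

Encoder and decoder layers are affine maps followed by ReLU. The decoder's
ReLU restricts reconstructions to non-negative values, which is consistent
with the inputs (kernel values, normalized k-mer frequencies, binary
fingerprint bits are all non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, dense_relu_backward, dense_relu_forward, he_init
from .data import InteractionNetwork
from .embedding import GraphEmbedding, build_dti_graph, fit_graph_factorization
from .features import FeatureMatrix
from .gip import SimilarityMatrix, gip_kernel


@dataclass
class AutoencoderModel:
    """Learned SAE parameters; decoder mirrors the encoder dims in reverse."""

    encoder_layers: list[tuple[np.ndarray, np.ndarray]]
    decoder_layers: list[tuple[np.ndarray, np.ndarray]]
    layer_dims: list[int]
    training_loss_trace: list[float] = field(default_factory=list)

    @property
    def code_dim(self) -> int:
        return self.layer_dims[-1]

    @property
    def input_dim(self) -> int:
        return self.layer_dims[0]


def _as_array(X) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def sae_encode(model: AutoencoderModel, X) -> np.ndarray | FeatureMatrix:
    """Map inputs to bottleneck codes through the encoder (affine + ReLU)."""
    codes, _ = dense_relu_forward(_as_array(X), model.encoder_layers)
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(codes, list(X.entity_ids), "embedding")
    return codes


def sae_decode(model: AutoencoderModel, Y) -> np.ndarray | FeatureMatrix:
    """Map bottleneck codes back to input space through the decoder."""
    recon, _ = dense_relu_forward(_as_array(Y), model.decoder_layers)
    if isinstance(Y, FeatureMatrix):
        return FeatureMatrix(recon, list(Y.entity_ids), "embedding")
    return recon


def reconstruction_loss(model: AutoencoderModel, X) -> float:
    """Mean squared reconstruction error of encode-then-decode."""
    X = _as_array(X)
    Z = sae_decode(model, sae_encode(model, X))
    return float(np.mean((Z - X) ** 2))


def _positive_he_layer(
    rng: np.random.Generator, d_in: int, d_out: int
) -> tuple[np.ndarray, np.ndarray]:
    """He-initialized layer adjusted for all-non-negative inputs.

    Every input this model sees is non-negative (kernel rows, frequencies,
    bits, ReLU codes), so a unit whose weight column has negative mean is
    silent on essentially every sample, receives no gradient, and stays dead
    for good. Flipping those columns' signs and starting biases slightly
    positive puts every unit in the active regime at initialization.
    """
    W = he_init(rng, d_in, d_out)
    flip = W.sum(axis=0) < 0
    W[:, flip] *= -1
    return W, np.full(d_out, 0.01)


def _init_model(layer_dims: list[int], rng: np.random.Generator) -> AutoencoderModel:
    enc = [
        _positive_he_layer(rng, d_in, d_out)
        for d_in, d_out in zip(layer_dims[:-1], layer_dims[1:])
    ]
    rev = list(reversed(layer_dims))
    dec = [
        _positive_he_layer(rng, d_in, d_out)
        for d_in, d_out in zip(rev[:-1], rev[1:])
    ]
    return AutoencoderModel(enc, dec, list(layer_dims))


def _train_reconstruction(
    X: np.ndarray,
    enc: list[tuple[np.ndarray, np.ndarray]],
    dec: list[tuple[np.ndarray, np.ndarray]],
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch Adam on MSE reconstruction; updates parameters in place."""
    params: list[np.ndarray] = []
    for W, b in enc + dec:
        params.extend((W, b))
    opt = Adam(params, lr=lr)
    n = X.shape[0]
    trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = X[order[start : start + batch_size]]
            codes, enc_acts = dense_relu_forward(batch, enc)
            recon, dec_acts = dense_relu_forward(codes, dec)
            diff = recon - batch
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError("autoencoder training diverged")
            epoch_loss += loss * batch.shape[0]
            d_recon = 2.0 * diff / diff.size
            d_codes, dec_grads = dense_relu_backward(d_recon, dec_acts, dec)
            _, enc_grads = dense_relu_backward(d_codes, enc_acts, enc)
            opt.step(enc_grads + dec_grads)
        trace.append(epoch_loss / n)
    return trace


def train_autoencoder(
    X,
    layer_dims: list[int],
    epochs: int = 30,
    learning_rate: float = 1e-3,
    seed: int = 0,
    batch_size: int = 32,
    pretrain: bool = True,
) -> AutoencoderModel:
    """Train a stacked autoencoder on rows of X by minimizing MSE reconstruction.

    Layers are pretrained greedily (each encoder/decoder pair as a one-layer
    autoencoder on the previous layer's codes), then the full stack is
    fine-tuned jointly. Fully deterministic given the seed.
    """
    X = _as_array(X)
    if layer_dims[0] != X.shape[1]:
        raise ValueError(
            f"layer_dims[0]={layer_dims[0]} must equal input dim {X.shape[1]}"
        )
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    model = _init_model(layer_dims, rng)
    trace: list[float] = []
    n_layers = len(model.encoder_layers)
    if pretrain and n_layers > 1:
        # greedy layer-wise pretraining at half the fine-tuning epochs
        pre_epochs = max(1, epochs // 2)
        H = X
        for i in range(n_layers):
            enc_i = [model.encoder_layers[i]]
            dec_i = [model.decoder_layers[n_layers - 1 - i]]
            trace += _train_reconstruction(
                H, enc_i, dec_i, pre_epochs, learning_rate, batch_size, rng
            )
            H, _ = dense_relu_forward(H, enc_i)
    trace += _train_reconstruction(
        X,
        model.encoder_layers,
        model.decoder_layers,
        epochs,
        learning_rate,
        batch_size,
        rng,
    )
    model.training_loss_trace = trace
    return model


def fuse_entity_features(
    gip: SimilarityMatrix,
    encoded_attributes: FeatureMatrix,
    embedding: GraphEmbedding,
    side: str,
) -> FeatureMatrix:
    """Concatenate [SAE-encoded block | graph-embedding row] per entity.

    All three inputs must agree on the side's entity ids and ordering; the
    embedding contributes its drug rows or target rows according to ``side``.
    """
    if side not in ("drug", "target"):
        raise ValueError(f"side must be 'drug' or 'target', got {side!r}")
    if gip.side != side:
        raise ValueError(f"GIP matrix is for side {gip.side!r}, expected {side!r}")
    ids = list(encoded_attributes.entity_ids)
    if gip.entity_ids != ids:
        raise ValueError("GIP and encoded-attribute entity ids disagree")
    emb_rows = embedding.drug_rows() if side == "drug" else embedding.target_rows()
    emb_ids = (
        embedding.node_ids[: embedding.n_drugs]
        if side == "drug"
        else embedding.node_ids[embedding.n_drugs :]
    )
    if emb_ids != ids:
        raise ValueError("embedding entity ids disagree with attribute ids")
    fused = np.hstack([encoded_attributes.X, emb_rows])
    return FeatureMatrix(fused, ids, "fused")


def build_fused_features(
    network: InteractionNetwork,
    drug_attributes: FeatureMatrix,
    protein_attributes: FeatureMatrix,
    config,
    seed: int = 0,
):
    """End-to-end compact feature construction for both sides of a network.

    Computes GIP kernels from the (possibly masked) network, trains one SAE
    per side on the [GIP row | attribute row] block, fits the joint graph
    factorization, and returns the two fused feature matrices along with the
    trained models. Seeds for the two SAEs and the embedding are derived from
    ``seed`` by fixed offsets.
    """
    gip_d = gip_kernel(network, "drug", config.gip_tau_prime)
    gip_t = gip_kernel(network, "target", config.gip_tau_prime)
    blocks = {}
    for side, gip_m, attrs, offset in (
        ("drug", gip_d, drug_attributes, 1),
        ("target", gip_t, protein_attributes, 2),
    ):
        X = np.hstack([gip_m.S, attrs.X])
        dims = [X.shape[1], *config.sae_hidden_dims, config.sae_code_dim]
        sae = train_autoencoder(
            X,
            dims,
            epochs=config.sae_epochs,
            learning_rate=config.sae_learning_rate,
            seed=(seed + offset) % 2**31,
            batch_size=config.sae_batch_size,
        )
        codes = dense_relu_forward(X, sae.encoder_layers)[0]
        blocks[side] = (gip_m, FeatureMatrix(codes, list(attrs.entity_ids), "embedding"), sae)
    graph = build_dti_graph(network)
    emb = fit_graph_factorization(
        graph,
        embedding_dim=config.gf_dim,
        lam=config.gf_lambda,
        learning_rate=config.gf_learning_rate,
        max_iterations=config.gf_max_iterations,
        tolerance=config.gf_tolerance,
        seed=(seed + 3) % 2**31,
        n_drugs=network.n_drugs,
    )
    fused_d = fuse_entity_features(blocks["drug"][0], blocks["drug"][1], emb, "drug")
    fused_p = fuse_entity_features(
        blocks["target"][0], blocks["target"][1], emb, "target"
    )
    models = {"sae_drug": blocks["drug"][2], "sae_target": blocks["target"][2],
              "embedding": emb}
    return fused_d, fused_p, models
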