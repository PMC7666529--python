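"""Pipeline hyperparameter container with declared defaults.

Every stage of the pipeline reads its knobs from :class:`PipelineConfig`.
Defaults: raw GIP bandwidth tau' = 1 (the convention in the interaction-
profile kernel literature); protein k-mer length 3 (8000-dimensional
composition, the standard choice for alignment-free protein features);
Morgan radius 2 folded to 1024 bits (ECFP4-style); graph factorization with
64 dimensions and L2 weight 0.1; SAE schedule input -> 256 -> 64; a 16-kernel
length-8 convolution head; and classification threshold 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    # GIP kernel
    gip_tau_prime: float = 1.0
    # protein k-mer features
    kmer_k: int = 3
    kmer_normalize: bool = True
    kmer_invalid_policy: str = "drop"
    # drug fingerprint features
    morgan_radius: int = 2
    morgan_bits: int = 1024
    # graph factorization
    gf_dim: int = 64
    gf_lambda: float = 0.1
    gf_learning_rate: float = 1e-2
    gf_max_iterations: int = 500
    gf_tolerance: float = 1e-6
    # stacked autoencoder (one per side, on [GIP row | attributes])
    sae_hidden_dims: tuple[int, ...] = (256,)
    sae_code_dim: int = 64
    sae_epochs: int = 30
    sae_learning_rate: float = 1e-3
    sae_batch_size: int = 32
    # 1-D CNN classifier
    cnn_n_kernels: int = 16
    cnn_kernel_len: int = 8
    cnn_pool_size: int = 2
    cnn_epochs: int = 60
    cnn_batch_size: int = 32
    cnn_learning_rate: float = 1e-3
    # evaluation
    threshold: float = 0.5
    cv_folds: int = 5

    def __post_init__(self) -> None:
        self.sae_hidden_dims = tuple(self.sae_hidden_dims)
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.kmer_k < 1 or self.kmer_k > 6:
            raise ValueError("kmer_k must be in 1..6")
        for name in (
            "gip_tau_prime", "gf_learning_rate", "sae_learning_rate",
            "cnn_learning_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "morgan_bits", "gf_dim", "sae_code_dim", "sae_epochs",
            "cnn_n_kernels", "cnn_kernel_len", "cnn_pool_size", "cnn_epochs",
            "cv_folds",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sae_hidden_dims"] = list(self.sae_hidden_dims)
        return d
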