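"""Gaussian interaction-profile (GIP) kernel similarity.

The GIP kernel measures how similarly two drugs (or two targets) behave in
the known interaction network: each drug's profile is its row of the binary
interaction matrix ``A``, each target's profile is its column, and

    S[i, j] = exp(-tau * ||V_i - V_j||^2)

with the bandwidth ``tau`` obtained by normalizing a raw hyperparameter
``tau'`` by the mean squared profile norm, so the kernel adapts to the
overall density of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import InteractionNetwork


@dataclass
class SimilarityMatrix:
    """Square symmetric kernel matrix for one side of the network."""

    S: np.ndarray
    entity_ids: list[str]
    side: str  # "drug" or "target"
    tau_prime: float
    tau: float

    def __post_init__(self) -> None:
        n = len(self.entity_ids)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")


def normalized_bandwidth(profiles: np.ndarray, tau_prime: float) -> float:
    """Normalize the raw bandwidth by the mean squared profile norm.

    Returns ``tau = tau' / ((1/n) * sum_i ||V_i||^2)`` where ``V_i`` are the
    rows of ``profiles``. An all-zero profile set makes the denominator
    vanish and is rejected.
    """
    if tau_prime <= 0:
        raise ValueError("tau_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("degenerate network: zero mean profile norm")
    return tau_prime / mean_sq_norm


def gip_kernel(
    network: InteractionNetwork, side: str, tau_prime: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel matrix over drugs (rows of A) or targets (columns of A).

    The kernel is computed once per unordered pair, so the result is exactly
    symmetric with a unit diagonal; entries lie in (0, 1].
    """
    if side == "drug":
        profiles = network.A.astype(float)
        ids = network.drug_ids
    elif side == "target":
        profiles = network.A.T.astype(float)
        ids = network.protein_ids
    else:
        raise ValueError(f"side must be 'drug' or 'target', got {side!r}")
    tau = normalized_bandwidth(profiles, tau_prime)
    if len(ids) == 1:
        S = np.ones((1, 1))
    else:
        sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
        S = np.exp(-tau * sq_dists)
    return SimilarityMatrix(S=S, entity_ids=list(ids), side=side,
                            tau_prime=tau_prime, tau=tau)
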