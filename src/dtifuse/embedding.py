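"""Graph-factorization embedding of the bipartite drug-target network.

Graph Factorization (GF) learns one low-dimensional vector per node by
minimizing

    eps(P, Q, lambda) = 1/2 * sum_{(i,j) in E} (P_ij - <Q_i, Q_j>)^2
                        + lambda/2 * sum_i ||Q_i||^2

over the factor matrix ``Q``, where ``P`` is the weighted adjacency matrix
and each unordered edge is counted once. The per-node gradient is

    d eps / d Q_i = - sum_{j in N_i} (P_ij - <Q_i, Q_j>) Q_j + lambda * Q_i

with ``N_i`` the neighbors of node ``i``. Drugs and targets are embedded
jointly in one bipartite graph; rows of ``Q`` are then split by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import InteractionNetwork


@dataclass
class WeightedGraph:
    """Symmetric weighted graph over an ordered node list (drugs then targets)."""

    node_ids: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (n, n):
            raise ValueError("adjacency matrix shape does not match node list")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.diagonal(self.P).any():
            raise ValueError("adjacency matrix must have a zero diagonal")
        if (self.P < 0).any():
            raise ValueError("edge weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Unordered node pairs (i < j) with positive weight."""
        iu, ju = np.where(np.triu(self.P, k=1) > 0)
        return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class GraphEmbedding:
    """Factor matrix Q (nodes x embedding_dim) with fit diagnostics."""

    Q: np.ndarray
    node_ids: list[str]
    lam: float
    final_loss: float
    n_iterations: int
    n_drugs: int = 0

    def drug_rows(self) -> np.ndarray:
        return self.Q[: self.n_drugs]

    def target_rows(self) -> np.ndarray:
        return self.Q[self.n_drugs :]


def build_dti_graph(network: InteractionNetwork) -> WeightedGraph:
    """Bipartite graph with n_d + n_p nodes and a unit-weight edge per known DTI."""
    n_d, n_p = network.n_drugs, network.n_targets
    P = np.zeros((n_d + n_p, n_d + n_p))
    P[:n_d, n_d:] = network.A
    P[n_d:, :n_d] = network.A.T
    return WeightedGraph(list(network.drug_ids) + list(network.protein_ids), P)


def _check_dims(graph: WeightedGraph, Q: np.ndarray, lam: float) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != graph.n_nodes:
        raise ValueError(
            f"Q has {Q.shape[0] if Q.ndim == 2 else '?'} rows, "
            f"graph has {graph.n_nodes} nodes"
        )
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return Q


def gf_loss(graph: WeightedGraph, Q: np.ndarray, lam: float) -> float:
    """Squared-error factorization loss plus L2 penalty, one term per edge."""
    Q = _check_dims(graph, Q, lam)
    mask = np.triu(graph.P, k=1) > 0
    residual = graph.P - Q @ Q.T
    edge_term = 0.5 * float((residual[mask] ** 2).sum())
    reg_term = 0.5 * lam * float((Q**2).sum())
    return edge_term + reg_term


def gf_gradient(
    graph: WeightedGraph, Q: np.ndarray, lam: float, node: int
) -> np.ndarray:
    """Gradient of :func:`gf_loss` with respect to row ``node`` of Q."""
    Q = _check_dims(graph, Q, lam)
    neighbors = np.where(graph.P[node] > 0)[0]
    grad = lam * Q[node]
    if neighbors.size:
        residual = graph.P[node, neighbors] - Q[neighbors] @ Q[node]
        grad = grad - residual @ Q[neighbors]
    return grad


def _full_gradient(graph: WeightedGraph, Q: np.ndarray, lam: float) -> np.ndarray:
    support = graph.P > 0
    residual = np.where(support, graph.P - Q @ Q.T, 0.0)
    return -residual @ Q + lam * Q


def fit_graph_factorization(
    graph: WeightedGraph,
    embedding_dim: int = 64,
    lam: float = 0.1,
    learning_rate: float = 1e-2,
    max_iterations: int = 500,
    tolerance: float = 1e-6,
    seed: int = 0,
    n_drugs: int = 0,
) -> GraphEmbedding:
    """Fit GF by full-batch gradient descent from a seeded Gaussian init.

    Stops when the relative loss decrease falls below ``tolerance`` or after
    ``max_iterations``. Deterministic given the seed.
    """
    if embedding_dim < 1:
        raise ValueError("embedding_dim must be >= 1")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    rng = np.random.default_rng(seed)
    Q = 0.1 * rng.standard_normal((graph.n_nodes, embedding_dim))
    loss = gf_loss(graph, Q, lam)
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        # overflow here just signals divergence, reported as an error below
        with np.errstate(over="ignore", invalid="ignore"):
            Q = Q - learning_rate * _full_gradient(graph, Q, lam)
            new_loss = gf_loss(graph, Q, lam)
        if not np.isfinite(new_loss):
            raise FloatingPointError("graph factorization diverged; reduce learning_rate")
        if loss > 0 and (loss - new_loss) / loss < tolerance and new_loss <= loss:
            loss = new_loss
            break
        loss = new_loss
    return GraphEmbedding(
        Q=Q,
        node_ids=list(graph.node_ids),
        lam=lam,
        final_loss=loss,
        n_iterations=n_iter,
        n_drugs=n_drugs,
    )
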