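"""Synthetic drug/protein/network generator with planted latent structure.

The generator emulates the statistical skeleton of a curated DTI benchmark:
drugs and targets live in a shared latent space, organised into clusters;
the probability that drug i binds target j is a logistic function of the
latent affinity U_i . V_j, with the offset calibrated by bisection so the
realized interaction density matches a target; attribute data (protein
sequences, drug fingerprints) are informative of the latent clusters, so a
pipeline that integrates attributes and network structure can recover the
planted interactions. Optional symmetric label noise flips each matrix
entry independently.

Every output is a pure function of (config, seed): each generator draws
from its own seeded stream, and cluster centers are re-derived from the
config seed so the three generators stay mutually consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (
    AMINO_ACIDS,
    DrugRecord,
    InteractionNetwork,
    ProteinRecord,
    write_drug_table,
    write_edge_list,
    write_fasta,
)

# logistic slope applied after standardizing latent affinities: large enough
# that the planted signal is close to separable before label noise
_SLOPE = 6.0
_CENTER_SD = 1.5
_WITHIN_SD = 0.5


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic benchmark draw."""

    n_drugs: int = 100
    n_targets: int = 80
    latent_dim: int = 8
    n_clusters: int = 4
    interaction_density_target: float = 0.05
    label_noise: float = 0.05
    fp_length: int = 128
    seq_length_range: tuple[int, int] = (150, 350)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_targets", "latent_dim", "n_clusters", "fp_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.interaction_density_target < 1):
            raise ValueError("interaction_density_target must be in (0, 1)")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        lo, hi = self.seq_length_range
        if lo < 1 or hi < lo:
            raise ValueError("seq_length_range must satisfy 1 <= min <= max")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _cluster_centers(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cluster centers for both sides, re-derivable by every generator."""
    rng = _rng(config, 1)
    drug_centers = _CENTER_SD * rng.standard_normal((config.n_clusters, config.latent_dim))
    target_centers = _CENTER_SD * rng.standard_normal((config.n_clusters, config.latent_dim))
    return drug_centers, target_centers


def _assign_clusters(rows: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Cluster index per row by highest affinity (smallest distance) to a center."""
    d2 = ((rows[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _calibrate_offset(logits: np.ndarray, density: float) -> float:
    """Bisection on the logistic offset so mean probability hits the density."""
    lo, hi = -60.0, 60.0
    if not (_sigmoid(logits + lo).mean() <= density <= _sigmoid(logits + hi).mean()):
        raise ValueError("interaction density target unreachable by offset calibration")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(logits + mid).mean() < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_latent_network(
    config: SyntheticConfig,
) -> tuple[InteractionNetwork, np.ndarray, np.ndarray]:
    """Draw the interaction network and its ground-truth latent factors.

    Returns ``(network, U, V)`` where U (drugs) and V (targets) are the
    planted latent matrices. Interaction probabilities are
    ``sigmoid(a * U_i.V_j + b)`` with ``a`` fixed by standardizing the
    affinities and ``b`` calibrated by bisection to the density target;
    each realized entry is then flipped independently with probability
    ``label_noise``.
    """
    drug_centers, target_centers = _cluster_centers(config)
    rng = _rng(config, 2)
    cd = rng.integers(0, config.n_clusters, config.n_drugs)
    ct = rng.integers(0, config.n_clusters, config.n_targets)
    U = drug_centers[cd] + _WITHIN_SD * rng.standard_normal(
        (config.n_drugs, config.latent_dim)
    )
    V = target_centers[ct] + _WITHIN_SD * rng.standard_normal(
        (config.n_targets, config.latent_dim)
    )
    raw = U @ V.T
    spread = raw.std()
    a = _SLOPE / spread if spread > 0 else 0.0
    b = _calibrate_offset(a * raw, config.interaction_density_target)
    probs = _sigmoid(a * raw + b)
    A = (rng.random(probs.shape) < probs).astype(np.int8)
    if config.label_noise > 0:
        flips = rng.random(probs.shape) < config.label_noise
        A = np.where(flips, 1 - A, A)
    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    protein_ids = [f"P{j:04d}" for j in range(config.n_targets)]
    return InteractionNetwork(A, drug_ids, protein_ids), U, V


def interaction_probabilities(
    config: SyntheticConfig, U: np.ndarray, V: np.ndarray
) -> np.ndarray:
    """Planted pre-noise interaction probabilities for given latent factors."""
    raw = U @ V.T
    spread = raw.std()
    a = _SLOPE / spread if spread > 0 else 0.0
    b = _calibrate_offset(a * raw, config.interaction_density_target)
    return _sigmoid(a * raw + b)


def _letter_profiles(config: SyntheticConfig) -> np.ndarray:
    """Per-cluster residue distributions with mostly disjoint preferred sets."""
    rng = _rng(config, 3)
    profiles = np.empty((config.n_clusters, 20))
    n_pref = 6
    for c in range(config.n_clusters):
        order = rng.permutation(20)
        p = np.full(20, 0.25 / (20 - n_pref))
        p[order[:n_pref]] = 0.75 / n_pref
        profiles[c] = p
    return profiles


def generate_sequences(config: SyntheticConfig, V: np.ndarray) -> list[ProteinRecord]:
    """Sample protein sequences whose residue composition marks the cluster.

    Each target is assigned to the latent cluster whose center is nearest to
    its V row; residues are then drawn i.i.d. from that cluster's letter
    distribution, with lengths uniform over ``seq_length_range``.
    """
    _, target_centers = _cluster_centers(config)
    clusters = _assign_clusters(np.asarray(V, dtype=float), target_centers)
    profiles = _letter_profiles(config)
    rng = _rng(config, 4)
    lo, hi = config.seq_length_range
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for j, c in enumerate(clusters):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[rng.choice(20, size=length, p=profiles[c])])
        records.append(ProteinRecord(f"P{j:04d}", seq))
    return records


def generate_fingerprints(
    config: SyntheticConfig, U: np.ndarray, flip_prob: float = 0.05
) -> list[DrugRecord]:
    """Binary fingerprints as cluster prototypes XOR independent bit flips."""
    drug_centers, _ = _cluster_centers(config)
    clusters = _assign_clusters(np.asarray(U, dtype=float), drug_centers)
    rng = _rng(config, 5)
    prototypes = (rng.random((config.n_clusters, config.fp_length)) < 0.5).astype(np.int8)
    records = []
    for i, c in enumerate(clusters):
        flips = rng.random(config.fp_length) < flip_prob
        fp = np.where(flips, 1 - prototypes[c], prototypes[c])
        records.append(DrugRecord(f"D{i:04d}", fingerprint=fp))
    return records


def simulate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[InteractionNetwork, list[DrugRecord], list[ProteinRecord], np.ndarray, np.ndarray]:
    """Generate the full (network, drugs, proteins) triple, optionally to disk.

    When ``out_dir`` is given, writes ``edges.tsv``, ``proteins.fasta``,
    ``drugs.tsv`` (fingerprint rows) and a ``ground_truth.json`` sidecar with
    the planted latent factors.
    """
    network, U, V = generate_latent_network(config)
    proteins = generate_sequences(config, V)
    drugs = generate_fingerprints(config, U)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_list(network, out / "edges.tsv")
        write_fasta(proteins, out / "proteins.fasta")
        write_drug_table(drugs, out / "drugs.tsv")
        sidecar = {
            "config": {
                "n_drugs": config.n_drugs,
                "n_targets": config.n_targets,
                "latent_dim": config.latent_dim,
                "n_clusters": config.n_clusters,
                "interaction_density_target": config.interaction_density_target,
                "label_noise": config.label_noise,
                "fp_length": config.fp_length,
                "seq_length_range": list(config.seq_length_range),
                "seed": config.seed,
            },
            "U": U.tolist(),
            "V": V.tolist(),
        }
        (out / "ground_truth.json").write_text(json.dumps(sidecar))
    return network, drugs, proteins, U, V
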