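"""Sample construction, cross-validation, metrics, ranking and cold start.

The evaluation protocol mirrors standard link-prediction practice for DTI
networks: known interactions are the positives; an equal number of unknown
(A = 0) pairs is drawn uniformly at random as presumed negatives; five-fold
cross-validation holds out one fifth of the positives per fold together with
freshly sampled test negatives disjoint from the training negatives.

Leakage control: within each fold, the GIP kernels, the graph embedding and
the autoencoders are all re-fit on a copy of the network with the held-out
positives zeroed, so no test edge can leak into the features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .cnn import LabeledPairSet, predict_scores, train_cnn
from .compact import build_fused_features
from .config import PipelineConfig
from .data import DrugRecord, InteractionNetwork, ProteinRecord
from .features import FeatureMatrix, kmer_features, morgan_features

METRIC_NAMES = ("auc", "aupr", "acc", "precision", "recall", "f1")


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: list[dict]
    mean: dict
    std: dict
    fold_assignments: list[dict]
    seed: int
    k: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
            "fold_assignments": self.fold_assignments,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class PredictionTable:
    """Ranked candidate interactions (rank 1 = highest score)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"drug_id", "protein_id", "score", "rank"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"prediction table needs columns {sorted(required)}")

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def __len__(self) -> int:
        return len(self.frame)


def sample_negative_pairs(
    network: InteractionNetwork,
    n_samples: int,
    seed: int,
    exclude: Optional[set[tuple[int, int]]] = None,
) -> list[tuple[int, int]]:
    """Uniform sample of unknown (A = 0) pairs, without replacement.

    The sample is disjoint from the known positives by construction and from
    the ``exclude`` set by filtering. Deterministic given the seed.
    """
    exclude = exclude or set()
    zeros = np.argwhere(network.A == 0)
    if exclude:
        keep = np.array(
            [tuple(p) not in exclude for p in zeros], dtype=bool
        )
        zeros = zeros[keep]
    if n_samples > len(zeros):
        raise ValueError(
            f"requested {n_samples} negatives but only {len(zeros)} unknown "
            "pairs are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=n_samples, replace=False)
    return [tuple(p) for p in zeros[np.sort(chosen)]]


def kfold_split(
    samples: LabeledPairSet, k: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Assign each sample to one of k folds (sizes differ by at most one).

    With ``stratified=True`` the balance holds within each class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(samples)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    groups = (
        [np.where(samples.labels == c)[0] for c in (0, 1)]
        if stratified
        else [np.arange(n)]
    )
    for idx in groups:
        if len(idx) < k:
            raise ValueError(
                f"need at least k={k} samples per class for the split, got {len(idx)}"
            )
        shuffled = rng.permutation(idx)
        for fold, chunk in enumerate(np.array_split(shuffled, k)):
            assignment[chunk] = fold
    return assignment


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals P(score_pos > score_neg) + P(tie)/2."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve (descending-score sweep)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("pr_auc needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def classification_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict:
    """Accuracy/precision/recall/F1 at ``score >= threshold``.

    Precision is reported as 0 (with ``no_positive_predictions`` flagged)
    when nothing is predicted positive.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    acc = (tp + tn) / len(labels) if len(labels) else 0.0
    no_pos_pred = (tp + fp) == 0
    precision = 0.0 if no_pos_pred else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return {
        "acc": acc,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "no_positive_predictions": no_pos_pred,
    }


def drug_attribute_features(
    drugs: Sequence[DrugRecord], config: PipelineConfig
) -> FeatureMatrix:
    """Fingerprint matrix; bit count inferred from precomputed fingerprints."""
    n_bits = config.morgan_bits
    if all(d.fingerprint is not None for d in drugs):
        n_bits = drugs[0].fingerprint.shape[0]
    return morgan_features(drugs, radius=config.morgan_radius, n_bits=n_bits)


def protein_attribute_features(
    proteins: Sequence[ProteinRecord], config: PipelineConfig
) -> FeatureMatrix:
    return kmer_features(
        proteins,
        k=config.kmer_k,
        normalize=config.kmer_normalize,
        invalid_policy=config.kmer_invalid_policy,
    )


def _fold_seed(seed: int, fold: int, tag: int) -> int:
    # single global seed fans out by fixed offsets
    return (seed + 7919 * (fold + 1) + 104729 * tag) % 2**31


def run_cross_validation(
    network: InteractionNetwork,
    drugs: Sequence[DrugRecord],
    proteins: Sequence[ProteinRecord],
    config: Optional[PipelineConfig] = None,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Leakage-safe k-fold cross-validation of the full pipeline.

    Per fold: the held-out positives are zeroed in A before GIP, embedding
    and autoencoder fitting; training uses the remaining positives plus an
    equal number of sampled negatives; the test set pairs the held-out
    positives with freshly sampled negatives disjoint from the training
    negatives. Returns per-fold and aggregate AUC/AUPR/Acc/Pre/Rec/F1.
    """
    config = config or PipelineConfig()
    drug_attr = drug_attribute_features(drugs, config)
    prot_attr = protein_attribute_features(proteins, config)
    if drug_attr.entity_ids != network.drug_ids:
        raise ValueError("drug record ids do not match network drug ids")
    if prot_attr.entity_ids != network.protein_ids:
        raise ValueError("protein record ids do not match network protein ids")
    positives = network.positive_pairs()
    pos_set = LabeledPairSet(positives, np.ones(len(positives)))
    folds = kfold_split(pos_set, k, seed=seed, stratified=False)
    per_fold = []
    assignments = []
    for fold in range(k):
        test_pos = [p for p, f in zip(positives, folds) if f == fold]
        train_pos = [p for p, f in zip(positives, folds) if f != fold]
        masked = network.masked(test_pos)
        fused_d, fused_p, _ = build_fused_features(
            masked, drug_attr, prot_attr, config, seed=_fold_seed(seed, fold, 1)
        )
        train_neg = sample_negative_pairs(
            network, len(train_pos), seed=_fold_seed(seed, fold, 2)
        )
        test_neg = sample_negative_pairs(
            network,
            len(test_pos),
            seed=_fold_seed(seed, fold, 3),
            exclude=set(train_neg),
        )
        train_set = LabeledPairSet(
            train_pos + train_neg,
            np.concatenate([np.ones(len(train_pos)), np.zeros(len(train_neg))]),
        )
        model = train_cnn(
            train_set, fused_d, fused_p, config, seed=_fold_seed(seed, fold, 4)
        )
        test_pairs = test_pos + test_neg
        labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
        scores = predict_scores(model, test_pairs, fused_d, fused_p)
        cls = classification_metrics(scores, labels, config.threshold)
        record = {
            "fold": fold,
            "auc": roc_auc(scores, labels),
            "aupr": pr_auc(scores, labels),
            "acc": cls["acc"],
            "precision": cls["precision"],
            "recall": cls["recall"],
            "f1": cls["f1"],
            "n_test_pos": len(test_pos),
            "n_test_neg": len(test_neg),
            "test_scores": [
                [network.drug_ids[i], network.protein_ids[j], float(s), int(y)]
                for (i, j), s, y in zip(test_pairs, scores, labels)
            ],
        }
        per_fold.append(record)
        assignments.extend(
            {"drug": network.drug_ids[i], "protein": network.protein_ids[j],
             "fold": fold}
            for i, j in test_pos
        )
    mean = {m: float(np.mean([r[m] for r in per_fold])) for m in METRIC_NAMES}
    std = {m: float(np.std([r[m] for r in per_fold])) for m in METRIC_NAMES}
    return CVReport(
        per_fold=per_fold,
        mean=mean,
        std=std,
        fold_assignments=assignments,
        seed=seed,
        k=k,
    )


def fit_full_model(
    network: InteractionNetwork,
    drugs: Sequence[DrugRecord],
    proteins: Sequence[ProteinRecord],
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
):
    """Train on all known positives + equal sampled negatives; return
    (model, fused_drug, fused_protein)."""
    config = config or PipelineConfig()
    drug_attr = drug_attribute_features(drugs, config)
    prot_attr = protein_attribute_features(proteins, config)
    fused_d, fused_p, _ = build_fused_features(
        network, drug_attr, prot_attr, config, seed=(seed + 11) % 2**31
    )
    positives = network.positive_pairs()
    negatives = sample_negative_pairs(
        network, len(positives), seed=(seed + 13) % 2**31
    )
    train_set = LabeledPairSet(
        positives + negatives,
        np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))]),
    )
    model = train_cnn(train_set, fused_d, fused_p, config, seed=(seed + 17) % 2**31)
    return model, fused_d, fused_p


def rank_novel_candidates(
    model,
    network: InteractionNetwork,
    fused_drug: FeatureMatrix,
    fused_protein: FeatureMatrix,
    top_n: int = 100,
) -> PredictionTable:
    """Score every unknown (A = 0) pair and return the top_n by score.

    Known interactions never appear in the output. Ties break
    lexicographically by (drug_id, protein_id).
    """
    unknown = [tuple(p) for p in np.argwhere(network.A == 0)]
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    if not unknown or top_n == 0:
        frame = pd.DataFrame(columns=["drug_id", "protein_id", "score", "rank"])
        return PredictionTable(frame)
    scores = predict_scores(model, unknown, fused_drug, fused_protein)
    frame = pd.DataFrame(
        {
            "drug_id": [network.drug_ids[i] for i, _ in unknown],
            "protein_id": [network.protein_ids[j] for _, j in unknown],
            "score": scores,
        }
    )
    frame = frame.sort_values(
        ["score", "drug_id", "protein_id"], ascending=[False, True, True]
    ).head(top_n)
    frame = frame.reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return PredictionTable(frame)


def attribute_similarity_vector(
    attributes: FeatureMatrix, query: np.ndarray, metric: Optional[str] = None
) -> np.ndarray:
    """Similarity of a query attribute vector to every stored entity.

    Tanimoto for binary fingerprints, cosine for k-mer frequencies; the
    metric is inferred from the feature kind when not given.
    """
    if metric is None:
        metric = "tanimoto" if attributes.feature_kind == "fingerprint" else "cosine"
    X = attributes.X
    q = np.asarray(query, dtype=float)
    if q.shape[0] != X.shape[1]:
        raise ValueError("query length does not match attribute dimension")
    if metric == "tanimoto":
        inter = (X * q[None, :]).sum(axis=1)
        union = X.sum(axis=1) + q.sum() - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(union > 0, inter / union, 0.0)
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1) * np.linalg.norm(q)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(norms > 0, X @ q / norms, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return sims


def cold_start_features(
    attributes: FeatureMatrix,
    fused: FeatureMatrix,
    query: np.ndarray,
    metric: Optional[str] = None,
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1),
) -> np.ndarray:
    """Fused vector for a new entity with no interaction profile.

    The three most attribute-similar existing entities are combined as
    0.6 * fused(1st) + 0.3 * fused(2nd) + 0.1 * fused(3rd); similarity ties
    break lexicographically by entity id. The combination is evaluated in
    the affine form f1 + w2*(f2-f1) + w3*(f3-f1) (identical since the
    weights sum to one), so identical neighbors reproduce their shared
    vector bit-exactly.
    """
    if attributes.entity_ids != fused.entity_ids:
        raise ValueError("attribute and fused matrices must share entity order")
    if len(attributes.entity_ids) < 3:
        raise ValueError("cold start needs at least 3 existing entities")
    w1, w2, w3 = weights
    if abs(w1 + w2 + w3 - 1.0) > 1e-12:
        raise ValueError("neighbor weights must sum to 1")
    sims = attribute_similarity_vector(attributes, query, metric)
    order = sorted(
        range(len(sims)), key=lambda i: (-sims[i], attributes.entity_ids[i])
    )
    f1, f2, f3 = (fused.X[i] for i in order[:3])
    return f1 + w2 * (f2 - f1) + w3 * (f3 - f1)


def shuffled_network(network: InteractionNetwork, seed: int) -> InteractionNetwork:
    """Null model: permute all entries of A, destroying the planted structure
    while preserving the number of positives."""
    rng = np.random.default_rng(seed)
    flat = network.A.flatten()
    rng.shuffle(flat)
    return InteractionNetwork(
        flat.reshape(network.A.shape), list(network.drug_ids), list(network.protein_ids)
    )
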