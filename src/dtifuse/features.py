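"""Attribute features: protein k-mer composition and drug Morgan fingerprints.

Proteins are represented by overlapping k-mer counts over the 20-letter
amino-acid alphabet (20^k dimensions, lexicographic column order), optionally
normalized to frequencies so sequences of different lengths are comparable
without alignment. Drugs are represented by hashed circular (Morgan/ECFP)
fingerprints folded to a fixed number of bits; records that already carry a
precomputed binary fingerprint pass through without touching the chemistry
backend.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import AMINO_ACIDS, DrugRecord, ProteinRecord

FEATURE_KINDS = ("kmer", "fingerprint", "gip_row", "embedding", "fused")


@dataclass
class FeatureMatrix:
    """Entities x features matrix with an ordered id registry."""

    X: np.ndarray
    entity_ids: list[str]
    feature_kind: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.entity_ids):
            raise ValueError("feature matrix row count must equal id count")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaN")

    def row(self, entity_id: str) -> np.ndarray:
        return self.X[self.entity_ids.index(entity_id)]


def kmer_vocabulary(k: int) -> list[str]:
    """All 20^k k-mers in lexicographic order of the standard alphabet."""
    return ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=k)]


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _kmer_counts(sequence: str, k: int, invalid_policy: str) -> np.ndarray:
    codes = np.array([_AA_INDEX.get(c, -1) for c in sequence], dtype=np.int64)
    if invalid_policy == "reject" and (codes < 0).any():
        bad = sorted({c for c in sequence if c not in _AA_INDEX})
        raise ValueError(f"sequence contains non-standard letters {bad}")
    n_windows = len(sequence) - k + 1
    # rolling base-20 index over valid windows; windows touching an invalid
    # letter are dropped so the feature space stays exactly 20^k
    idx = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for offset in range(k):
        window_codes = codes[offset : offset + n_windows]
        idx = idx * 20 + np.where(window_codes < 0, 0, window_codes)
        valid &= window_codes >= 0
    return np.bincount(idx[valid], minlength=20**k).astype(float)


def kmer_features(
    proteins: Sequence[ProteinRecord],
    k: int = 3,
    normalize: bool = True,
    invalid_policy: str = "drop",
) -> FeatureMatrix:
    """Overlapping k-mer composition vectors for a protein collection.

    Parameters
    ----------
    k
        Substring length (1-4 are practical; the dimension is 20^k).
    normalize
        Divide each row by its total k-mer count so rows sum to 1.
    invalid_policy
        "drop": k-mers containing a non-standard letter (B, J, O, U, X, Z, ...)
        are skipped; "reject": such sequences raise an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if invalid_policy not in ("drop", "reject"):
        raise ValueError("invalid_policy must be 'drop' or 'reject'")
    rows = np.zeros((len(proteins), 20**k))
    for r, rec in enumerate(proteins):
        if len(rec.sequence) < k:
            raise ValueError(
                f"protein {rec.protein_id!r}: sequence shorter than k={k}"
            )
        counts = _kmer_counts(rec.sequence, k, invalid_policy)
        total = counts.sum()
        if total == 0:
            raise ValueError(
                f"protein {rec.protein_id!r}: every k-mer contains a "
                "non-standard letter"
            )
        rows[r] = counts / total if normalize else counts
    return FeatureMatrix(rows, [p.protein_id for p in proteins], "kmer")


def morgan_features(
    drugs: Sequence[DrugRecord], radius: int = 2, n_bits: int = 1024
) -> FeatureMatrix:
    """Binary circular-fingerprint matrix for a drug collection.

    SMILES records are fingerprinted with the RDKit Morgan generator
    (ECFP-style, folded to ``n_bits``); records carrying a precomputed
    fingerprint pass through unchanged and must all have length ``n_bits``.
    The chemistry backend is only imported when a SMILES record is present.
    """
    rows = np.zeros((len(drugs), n_bits))
    generator = None
    for r, rec in enumerate(drugs):
        if rec.fingerprint is not None:
            if rec.fingerprint.shape[0] != n_bits:
                raise ValueError(
                    f"drug {rec.drug_id!r}: fingerprint length "
                    f"{rec.fingerprint.shape[0]} != n_bits {n_bits}"
                )
            rows[r] = rec.fingerprint
            continue
        if generator is None:
            from rdkit import Chem
            from rdkit.Chem import rdFingerprintGenerator

            generator = rdFingerprintGenerator.GetMorganGenerator(
                radius=radius, fpSize=n_bits
            )
            _mol_from_smiles = Chem.MolFromSmiles
        mol = _mol_from_smiles(rec.smiles)
        if mol is None:
            raise ValueError(f"drug {rec.drug_id!r}: unparseable SMILES {rec.smiles!r}")
        fp = generator.GetFingerprintAsNumPy(mol)
        rows[r] = fp.astype(float)
    return FeatureMatrix(rows, [d.drug_id for d in drugs], "fingerprint")
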