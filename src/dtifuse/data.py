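"""Canonical in-memory data model and readers/writers for the standard formats.

The hub type is :class:`InteractionNetwork`: a binary drug x target matrix
``A`` whose rows are drug interaction profiles and whose columns are target
interaction profiles, together with ordered id registries for both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard amino-acid one-letter codes, in lexicographic order."""


class ParseError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass
class DrugRecord:
    """A drug identified by an opaque id, carrying a SMILES string and/or a
    precomputed binary fingerprint vector."""

    drug_id: str
    smiles: Optional[str] = None
    fingerprint: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.smiles is None and self.fingerprint is None:
            raise ValueError(
                f"drug {self.drug_id!r}: need at least one of smiles/fingerprint"
            )
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"drug {self.drug_id!r}: fingerprint must be binary")
            self.fingerprint = fp.astype(np.int8)


@dataclass
class ProteinRecord:
    """A protein identified by an opaque id with an amino-acid sequence.

    Sequences are upper-cased on construction. Letters outside the standard
    20-letter alphabet are kept here; the k-mer featurizer applies the
    configured policy (drop affected k-mers, or reject the sequence).
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        self.sequence = self.sequence.upper()


@dataclass
class InteractionNetwork:
    """Binary drug-target interaction matrix with id registries.

    ``A[i, j] == 1`` iff drug ``drug_ids[i]`` is known to interact with
    target ``protein_ids[j]``. Row order matches ``drug_ids`` and column
    order matches ``protein_ids``.
    """

    A: np.ndarray
    drug_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.A.shape != (len(self.drug_ids), len(self.protein_ids)):
            raise ValueError(
                f"A shape {self.A.shape} does not match id registries "
                f"({len(self.drug_ids)} drugs, {len(self.protein_ids)} targets)"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A entries must be 0 or 1")
        for name, ids in (("drug", self.drug_ids), ("protein", self.protein_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")

    @property
    def n_drugs(self) -> int:
        return self.A.shape[0]

    @property
    def n_targets(self) -> int:
        return self.A.shape[1]

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) with A[i, j] == 1, in row-major order."""
        return [tuple(p) for p in np.argwhere(self.A == 1)]

    def masked(self, pairs: Iterable[tuple[int, int]]) -> "InteractionNetwork":
        """Copy of the network with the given positive pairs zeroed out."""
        A = self.A.copy()
        for i, j in pairs:
            A[i, j] = 0
        return InteractionNetwork(A, list(self.drug_ids), list(self.protein_ids))


def _split_columns(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [c.strip() for c in line.split(sep)]


def read_edge_list(
    path: str | Path,
    drug_ids: Optional[Sequence[str]] = None,
    protein_ids: Optional[Sequence[str]] = None,
) -> InteractionNetwork:
    """Read a two-column (drug_id, protein_id) edge list into a network.

    The file may be tab- or comma-separated. Optional id lists fix the
    matrix ordering; ids in the file but absent from a provided list raise
    a :class:`ParseError`. Without lists, ids are registered in order of
    first appearance. Duplicate edges collapse (the matrix is binary).
    """
    edges: list[tuple[str, str]] = []
    seen_drugs: dict[str, None] = {}
    seen_prots: dict[str, None] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = _split_columns(line)
            if len(cols) != 2 or not all(cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected two columns "
                    f"(drug_id, protein_id), got {line!r}"
                )
            d, p = cols
            edges.append((d, p))
            seen_drugs.setdefault(d)
            seen_prots.setdefault(p)
    d_ids = list(drug_ids) if drug_ids is not None else list(seen_drugs)
    p_ids = list(protein_ids) if protein_ids is not None else list(seen_prots)
    d_index = {d: i for i, d in enumerate(d_ids)}
    p_index = {p: j for j, p in enumerate(p_ids)}
    A = np.zeros((len(d_ids), len(p_ids)), dtype=np.int8)
    for d, p in edges:
        if d not in d_index:
            raise ParseError(f"{path}: drug id {d!r} not in the provided drug_ids")
        if p not in p_index:
            raise ParseError(
                f"{path}: protein id {p!r} not in the provided protein_ids"
            )
        A[d_index[d], p_index[p]] = 1
    return InteractionNetwork(A, d_ids, p_ids)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    """Write the positive pairs of a network as a tab-separated edge list."""
    with open(path, "w") as fh:
        for i, j in network.positive_pairs():
            fh.write(f"{network.drug_ids[i]}\t{network.protein_ids[j]}\n")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the protein id;
    sequence lines are concatenated and upper-cased. Empty sequences and
    text before the first header are parse errors.
    """
    with open(path) as fh:
        head = fh.read(1)
        if head and head not in (">", ";"):
            raise ParseError(f"{path}: sequence data before the first FASTA header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in proteins:
            fh.write(f">{rec.protein_id}\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def read_smiles_table(path: str | Path) -> list[DrugRecord]:
    """Read a two-column delimited table of (drug_id, SMILES).

    A third form is accepted for chemistry-free runs: rows whose second
    column is a string over {0,1} of uniform length are interpreted as
    precomputed binary fingerprints instead of SMILES.
    """
    records: list[DrugRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = _split_columns(line)
            if len(cols) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected two columns (drug_id, SMILES)"
                )
            drug_id, payload = cols
            if not payload:
                raise ParseError(f"{path}: line {lineno}: blank SMILES for {drug_id!r}")
            if drug_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate drug id {drug_id!r}")
            seen.add(drug_id)
            if len(payload) > 4 and set(payload) <= {"0", "1"}:
                fp = np.frombuffer(payload.encode(), dtype=np.uint8) - ord("0")
                records.append(DrugRecord(drug_id, fingerprint=fp))
            else:
                records.append(DrugRecord(drug_id, smiles=payload))
    return records


def write_drug_table(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    """Write drugs as a two-column table (SMILES, or a 0/1 fingerprint string)."""
    with open(path, "w") as fh:
        for rec in drugs:
            if rec.smiles is not None:
                payload = rec.smiles
            else:
                payload = "".join(map(str, rec.fingerprint.tolist()))
            fh.write(f"{rec.drug_id}\t{payload}\n")


def write_predictions(table, path: str | Path) -> None:
    """Write a prediction table as CSV with columns drug_id,protein_id,score,rank.

    Rows are sorted by descending score; ties break lexicographically by
    (drug_id, protein_id) so output files are deterministic. Rank 1 is the
    highest score. NaN scores are rejected.
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    if len(df) and df["score"].isna().any():
        raise ValueError("prediction table contains NaN scores")
    if len(df):
        df = df.sort_values(
            ["score", "drug_id", "protein_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df = pd.DataFrame(columns=["drug_id", "protein_id", "score", "rank"])
    df.to_csv(path, index=False, columns=["drug_id", "protein_id", "score", "rank"])
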