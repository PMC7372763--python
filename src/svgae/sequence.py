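"""Protein sequence parsing and conjoint-triad (CT) feature coding.

The CT descriptor collapses the 20 canonical amino acids into seven classes
defined by side-chain dipole and volume, then counts every ordered 3-mer of
class labels obtained by sliding a window of width three along the sequence
one residue at a time.  With seven classes there are 7**3 = 343 triad types,
so every protein maps to a fixed 343-dimensional vector regardless of length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CT_DIM = 343

#: Seven-class amino-acid alphabet (dipole / side-chain volume grouping).
#: C1 {A,G,V}, C2 {I,L,F,P}, C3 {Y,M,T,S}, C4 {H,N,Q,W}, C5 {R,K}, C6 {D,E}, C7 {C}
CT_CLASSES: dict[str, int] = {}
for _cls, _letters in enumerate(["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"], start=1):
    for _aa in _letters:
        CT_CLASSES[_aa] = _cls

CANONICAL_RESIDUES = frozenset(CT_CLASSES)


class InvalidResidueError(ValueError):
    """A sequence contains a letter outside the 20 canonical amino acids."""

    def __init__(self, residue: str, position: int | None = None,
                 record_id: str | None = None):
        self.residue = residue
        self.position = position
        self.record_id = record_id
        where = f" at position {position}" if position is not None else ""
        who = f" in record '{record_id}'" if record_id else ""
        super().__init__(f"invalid residue '{residue}'{where}{who}: "
                         f"not one of the 20 canonical amino acids")


@dataclass
class ProteinRecord:
    """A protein with identifier, sequence and optional filter annotations."""

    id: str
    sequence: str
    annotations: dict | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein record '{self.id}' has an empty sequence")
        self.sequence = self.sequence.upper()

    @property
    def species(self) -> str | None:
        return (self.annotations or {}).get("species")

    @property
    def localizations(self) -> list[str]:
        return list((self.annotations or {}).get("localizations", []))

    @property
    def is_fragment(self) -> bool:
        return bool((self.annotations or {}).get("is_fragment", False))


@dataclass
class CTVector:
    """Conjoint-triad counts for a single sequence.

    ``counts[(a-1)*49 + (b-1)*7 + (c-1)]`` is the number of windows whose
    residues fall in classes (a, b, c).  For a sequence of length L over
    canonical residues the raw counts sum to max(0, L - 2).
    """

    counts: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (CT_DIM,):
            raise ValueError(f"CT vector must have length {CT_DIM}, "
                             f"got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("CT counts must be non-negative")


def classify_residue(aa: str) -> int:
    """Map one canonical amino-acid letter to its conjoint-triad class (1..7)."""
    try:
        return CT_CLASSES[aa.upper()]
    except KeyError:
        raise InvalidResidueError(aa) from None


def triad_index(a: int, b: int, c: int) -> int:
    """Flat index of ordered triad (a, b, c), classes in 1..7."""
    return (a - 1) * 49 + (b - 1) * 7 + (c - 1)


def encode_ct(record: ProteinRecord) -> CTVector:
    """Encode one protein as its 343-entry conjoint-triad count vector.

    Raises :class:`InvalidResidueError` for non-canonical letters (U, X, B,
    Z, ...).  Sequences shorter than three residues yield an all-zero vector
    with a warning; upstream dataset filters normally remove them.
    """
    seq = record.sequence
    classes = np.empty(len(seq), dtype=np.int64)
    for i, aa in enumerate(seq):
        cls = CT_CLASSES.get(aa)
        if cls is None:
            raise InvalidResidueError(aa, position=i, record_id=record.id)
        classes[i] = cls

    counts = np.zeros(CT_DIM, dtype=float)
    if len(seq) < 3:
        logger.warning("sequence '%s' has length %d < 3; CT vector is all zero",
                       record.id, len(seq))
        return CTVector(counts=counts, source_length=len(seq))

    flat = ((classes[:-2] - 1) * 49 + (classes[1:-1] - 1) * 7 + (classes[2:] - 1))
    np.add.at(counts, flat, 1.0)
    return CTVector(counts=counts, source_length=len(seq))


@dataclass
class FeatureMatrix:
    """N x 343 matrix of CT features, row order matching the node order."""

    ids: list[str]
    X: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.ids), CT_DIM):
            raise ValueError(f"feature matrix shape {self.X.shape} does not match "
                             f"{len(self.ids)} ids x {CT_DIM} features")


def build_feature_matrix(records: Sequence[ProteinRecord],
                         normalize: bool = True) -> FeatureMatrix:
    """Stack per-protein CT vectors into an N x 343 matrix.

    With ``normalize`` each row is divided by its sum (triad frequencies
    rather than raw counts); all-zero rows are left at zero.  Row i always
    corresponds to ``records[i]`` — no hidden sorting.
    """
    if not records:
        raise ValueError("cannot build a feature matrix from zero records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = {i for i in ids if i in seen or seen.add(i)}
        raise ValueError(f"duplicate protein ids: {sorted(dupes)}")
    X = np.vstack([encode_ct(r).counts for r in records])
    if normalize:
        sums = X.sum(axis=1, keepdims=True)
        np.divide(X, sums, out=X, where=sums > 0)
    return FeatureMatrix(ids=ids, X=X, normalized=normalize)


# ---------------------------------------------------------------------------
# FASTA and TSV I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; sequences
    are uppercased.  Duplicate ids raise a ``ValueError``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id '{rec.id}' in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (standard dialect, 60-column wrapping)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                   for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def feature_matrix_to_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    """Export a feature matrix as TSV: protein id plus 343 triad columns."""
    import pandas as pd

    cols = [f"t{a}{b}{c}" for a in range(1, 8) for b in range(1, 8)
            for c in range(1, 8)]
    df = pd.DataFrame(fm.X, index=pd.Index(fm.ids, name="id"), columns=cols)
    df.to_csv(path, sep="\t")
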