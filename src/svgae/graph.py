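"""Signed interaction graphs: negative-sample filters, adjacency, splits.

The interaction network is undirected.  Observed interactions are positive
edges (+1).  High-confidence non-interactions — pairs of proteins confined
to different subcellular compartments — are negative edges (−1).  Every
other pair is of uncertain status (0) and is excluded from the
reconstruction loss via a confidence mask.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .sequence import CANONICAL_RESIDUES, ProteinRecord

logger = logging.getLogger(__name__)

POSITIVE = 1
HIGH_NEGATIVE = -1

#: Localization qualifiers that mark a subcellular annotation as uncertain.
AMBIGUOUS_LOCALIZATION_TERMS = ("potential", "probable", "probably", "maybe",
                                "by similarity")

MIN_SEQUENCE_LENGTH = 50

Pair = tuple[str, str, int]


def _key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeList:
    """Undirected labelled protein pairs; labels +1 (positive) / −1 (high-negative)."""

    pairs: list[Pair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for a, b, lab in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) is not allowed")
            if lab not in (POSITIVE, HIGH_NEGATIVE):
                raise ValueError(f"edge label must be +1 or -1, got {lab}")
            k = _key(a, b)
            if k in seen:
                if seen[k] != lab:
                    raise ValueError(f"conflicting labels for pair {k}")
                raise ValueError(f"duplicate pair {k}")
            seen[k] = lab

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def positives(self) -> list[Pair]:
        return [p for p in self.pairs if p[2] == POSITIVE]

    @property
    def negatives(self) -> list[Pair]:
        return [p for p in self.pairs if p[2] == HIGH_NEGATIVE]

    def keys(self) -> set[tuple[str, str]]:
        return {_key(a, b) for a, b, _ in self.pairs}

    def ids(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.pairs:
            out.add(a)
            out.add(b)
        return out


@dataclass
class SignedAdjacency:
    """Symmetric N x N signed adjacency with unit diagonal and confidence mask.

    ``matrix`` entries are +1 (observed interaction), −1 (high-confidence
    non-interaction) or 0 (uncertain) off the diagonal, +1 on the diagonal
    (self-loops).  ``confidence_mask`` is True exactly on the off-diagonal
    ±1 cells — the high-confidence subset the reconstruction loss sees.
    """

    matrix: np.ndarray
    confidence_mask: np.ndarray
    node_index: list[str]

    def __post_init__(self) -> None:
        n = len(self.node_index)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.confidence_mask = np.asarray(self.confidence_mask, dtype=bool)
        if self.matrix.shape != (n, n) or self.confidence_mask.shape != (n, n):
            raise ValueError("adjacency / mask shape does not match node count")
        self._index = {pid: i for i, pid in enumerate(self.node_index)}

    @property
    def n(self) -> int:
        return len(self.node_index)

    def index_of(self, pid: str) -> int:
        try:
            return self._index[pid]
        except KeyError:
            raise KeyError(f"unknown protein id '{pid}'") from None

    def unsigned(self) -> "SignedAdjacency":
        """Ablation twin: every ±1 edge becomes +1; identical mask."""
        return SignedAdjacency(matrix=np.abs(self.matrix),
                               confidence_mask=self.confidence_mask.copy(),
                               node_index=list(self.node_index))


def build_signed_adjacency(ids: Sequence[str], edges: EdgeList) -> SignedAdjacency:
    """Assemble the signed adjacency matrix A and its confidence mask.

    Entry (i, j) = (j, i) = +1 for a positive pair, −1 for a high-negative
    pair, 0 otherwise; the diagonal is +1 (self-loops added as the identity).
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("node ids must be unique")
    index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=np.float64)
    mask = np.zeros((n, n), dtype=bool)
    for a, b, lab in edges:
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise ValueError(f"edge references unknown protein id {exc}") from None
        A[i, j] = A[j, i] = float(lab)
        mask[i, j] = mask[j, i] = True
    np.fill_diagonal(A, 1.0)
    np.fill_diagonal(mask, False)
    return SignedAdjacency(matrix=A, confidence_mask=mask, node_index=ids)


# ---------------------------------------------------------------------------
# Negative-sample construction


def filter_negative_candidates(records: Sequence[ProteinRecord],
                               species: str | None = "human",
                               ) -> list[ProteinRecord]:
    """Apply the five high-confidence negative-candidate criteria.

    A record survives only if: (1) its species tag equals ``species`` (skip
    by passing ``species=None``); (2) no localization term carries an
    ambiguity qualifier ("potential", "probable", ...); (3) it has exactly
    one localization term; (4) it is not a fragment and is at least 50
    residues long; (5) its sequence contains only canonical residues (no U,
    X, ...).  Per-criterion rejection counts are logged; the function is a
    pure filter and idempotent.
    """
    rejections: Counter[str] = Counter()
    kept: list[ProteinRecord] = []
    for rec in records:
        locs = rec.localizations
        if species is not None and rec.species != species:
            rejections["species"] += 1
        elif any(term in loc.lower() for loc in locs
                 for term in AMBIGUOUS_LOCALIZATION_TERMS):
            rejections["ambiguous_localization"] += 1
        elif len(locs) != 1:
            rejections["not_unique_localization"] += 1
        elif rec.is_fragment or len(rec.sequence) < MIN_SEQUENCE_LENGTH:
            rejections["fragment_or_short"] += 1
        elif not set(rec.sequence) <= CANONICAL_RESIDUES:
            rejections["nonstandard_residue"] += 1
        else:
            kept.append(rec)
    logger.info("negative-candidate filter kept %d/%d records; rejections: %s",
                len(kept), len(records), dict(rejections))
    return kept


def count_cross_location_pairs(records: Sequence[ProteinRecord],
                               positives: EdgeList) -> int:
    """Number of unordered cross-compartment pairs not already positive."""
    loc_sizes = Counter(rec.localizations[0] for rec in records)
    n = len(records)
    cross = (n * n - sum(k * k for k in loc_sizes.values())) // 2
    loc_by_id = {rec.id: rec.localizations[0] for rec in records}
    overlap = 0
    for a, b, _ in positives.positives:
        la, lb = loc_by_id.get(a), loc_by_id.get(b)
        if la is not None and lb is not None and la != lb:
            overlap += 1
    return cross - overlap


def generate_negative_pairs(records: Sequence[ProteinRecord], n_pairs: int,
                            positives: EdgeList, seed: int) -> EdgeList:
    """Sample high-confidence negative pairs from filtered candidates.

    Pairs are drawn uniformly at random subject to: the two proteins carry
    different (single) localization labels, the pair is not an observed
    positive, no self-pairs and no duplicates.  Deterministic given ``seed``.
    Raises if fewer than ``n_pairs`` valid pairs exist, reporting the
    attainable maximum.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    for rec in records:
        if len(rec.localizations) != 1:
            raise ValueError(f"record '{rec.id}' lacks a unique localization; "
                             "run filter_negative_candidates first")
    attainable = count_cross_location_pairs(records, positives)
    if attainable < n_pairs:
        raise ValueError(f"only {attainable} valid negative pairs exist, "
                         f"{n_pairs} requested")
    rng = np.random.default_rng(seed)
    ids = [rec.id for rec in records]
    locs = [rec.localizations[0] for rec in records]
    pos_keys = positives.keys()
    chosen: set[tuple[str, str]] = set()
    out: list[Pair] = []
    n = len(records)
    # Rejection sampling is uniform over the valid-pair set; fall back to
    # exhaustive enumeration when the pool is nearly exhausted.
    max_rejects = 200 * n_pairs + 1000
    rejects = 0
    while len(out) < n_pairs and rejects < max_rejects:
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i == j or locs[i] == locs[j]:
            rejects += 1
            continue
        k = _key(ids[i], ids[j])
        if k in pos_keys or k in chosen:
            rejects += 1
            continue
        chosen.add(k)
        out.append((k[0], k[1], HIGH_NEGATIVE))
    if len(out) < n_pairs:
        remaining = [
            _key(ids[i], ids[j])
            for i in range(n) for j in range(i + 1, n)
            if locs[i] != locs[j]
            and _key(ids[i], ids[j]) not in pos_keys
            and _key(ids[i], ids[j]) not in chosen
        ]
        take = rng.choice(len(remaining), size=n_pairs - len(out), replace=False)
        for t in sorted(int(x) for x in take):
            a, b = remaining[t]
            out.append((a, b, HIGH_NEGATIVE))
    return EdgeList(pairs=out)


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitSpec:
    """One 80/20 train/test realization with 5-fold assignments on the train part."""

    train: EdgeList
    test: EdgeList
    fold_assignments: list[int]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed,
                   "train": [list(p) for p in self.train],
                   "test": [list(p) for p in self.test],
                   "fold_assignments": self.fold_assignments}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        payload = json.loads(Path(path).read_text())
        return cls(train=EdgeList([tuple(p) for p in payload["train"]]),
                   test=EdgeList([tuple(p) for p in payload["test"]]),
                   fold_assignments=list(payload["fold_assignments"]),
                   seed=int(payload["seed"]))


def split_edges(edges: EdgeList, test_fraction: float = 0.2, n_repeats: int = 5,
                n_folds: int = 5, seed: int = 0) -> list[SplitSpec]:
    """Repeated stratified train/test splits with k-fold assignments.

    Each repeat holds out ``test_fraction`` of the labelled pairs,
    stratified by label so the positive:negative ratio is preserved; the
    training pairs are further partitioned into ``n_folds`` stratified folds
    used for checkpoint selection.  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.array([lab for _, _, lab in edges])
    if len(set(labels.tolist())) < 2:
        raise ValueError("both positive and high-negative pairs are required")
    pairs = list(edges)
    ss = np.random.SeedSequence(seed)
    out: list[SplitSpec] = []
    for rep, child in enumerate(ss.spawn(n_repeats)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        idx = np.arange(len(pairs))
        try:
            tr, te = train_test_split(idx, test_size=test_fraction,
                                      stratify=labels, random_state=rep_seed)
        except ValueError as exc:
            raise ValueError(f"too few edges to stratify: {exc}") from None
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rep_seed)
        folds = np.empty(len(tr), dtype=int)
        for f, (_, val_idx) in enumerate(skf.split(tr, labels[tr]), start=1):
            folds[val_idx] = f
        out.append(SplitSpec(train=EdgeList([pairs[i] for i in tr]),
                             test=EdgeList([pairs[i] for i in te]),
                             fold_assignments=folds.tolist(),
                             seed=rep_seed))
    return out


def coverage_sample(edges: EdgeList, coverage: float, seed: int) -> EdgeList:
    """Per-protein sparsification of the training graph.

    For every protein, independently for its positive and its high-negative
    incident edges, ``ceil(coverage * degree)`` edges are retained at random
    (so any protein with at least one edge of a label keeps at least one).
    An edge retained from either endpoint's draw survives.  ``coverage=1``
    returns the input unchanged.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    if coverage == 1.0:
        return EdgeList(pairs=list(edges))
    rng = np.random.default_rng(seed)
    incident: dict[tuple[str, int], list[int]] = {}
    for e_idx, (a, b, lab) in enumerate(edges):
        incident.setdefault((a, lab), []).append(e_idx)
        incident.setdefault((b, lab), []).append(e_idx)
    keep: set[int] = set()
    for (_pid, _lab), e_idxs in sorted(incident.items()):
        k = ceil(coverage * len(e_idxs))
        picked = rng.choice(len(e_idxs), size=k, replace=False)
        keep.update(e_idxs[int(p)] for p in picked)
    pairs = list(edges)
    return EdgeList(pairs=[pairs[i] for i in sorted(keep)])


# ---------------------------------------------------------------------------
# TSV I/O


def read_edge_tsv(path: str | Path) -> EdgeList:
    """Read `id_a<TAB>id_b<TAB>label` rows (label +1/-1; optional header)."""
    pairs: list[Pair] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated "
                                 f"fields, got {len(parts)}")
            a, b, lab = parts
            if line_no == 1 and lab.lstrip("+-").lower() in ("label", "sign"):
                continue
            pairs.append((a, b, int(lab)))
    return EdgeList(pairs=pairs)


def write_edge_tsv(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for a, b, lab in edges:
            fh.write(f"{a}\t{b}\t{lab}\n")


def read_annotation_tsv(path: str | Path) -> dict[str, dict]:
    """Read `id<TAB>species<TAB>loc1;loc2<TAB>fragment(0/1)` annotations."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 fields")
            pid, species, locs, frag = parts
            if line_no == 1 and pid.lower() == "id":
                continue
            out[pid] = {"species": species,
                        "localizations": [l for l in locs.split(";") if l],
                        "is_fragment": frag.strip() == "1"}
    return out


def write_annotation_tsv(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tlocalizations\tfragment\n")
        for rec in records:
            ann = rec.annotations or {}
            fh.write(f"{rec.id}\t{ann.get('species', '')}\t"
                     f"{';'.join(ann.get('localizations', []))}\t"
                     f"{1 if ann.get('is_fragment') else 0}\n")


def attach_annotations(records: Sequence[ProteinRecord],
                       annotations: dict[str, dict]) -> list[ProteinRecord]:
    """Return records with annotations merged in (missing ids left as-is)."""
    return [ProteinRecord(id=r.id, sequence=r.sequence,
                          annotations=annotations.get(r.id, r.annotations))
            for r in records]
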