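"""Self-contained synthetic PPI datasets with planted, learnable structure.

The generator emulates the statistical shape the pipeline assumes:

* an undirected interaction graph with community (block) structure —
  proteins inside a block interact densely, across blocks rarely;
* per-protein subcellular "compartment" labels, independent of the blocks,
  that drive high-confidence negative-pair construction (two proteins in
  different compartments that were never observed to interact);
* amino-acid sequences whose conjoint-triad composition is biased by block
  identity, so sequence features are informative for link prediction.

Blocks and compartments are deliberately decoupled: a model cannot solve
the task from compartment labels alone, it must combine graph structure
with sequence features.  All records carry annotations that pass the
negative-candidate filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import derive_seed
from .graph import (EdgeList, HIGH_NEGATIVE, POSITIVE,
                    count_cross_location_pairs, generate_negative_pairs)
from .sequence import CT_CLASSES, ProteinRecord

# residues by conjoint-triad class, index 0 = class 1
_CLASS_RESIDUES = [[aa for aa, c in CT_CLASSES.items() if c == cls]
                   for cls in range(1, 8)]


@dataclass
class SyntheticSpec:
    """Parameters of the planted dataset.

    Defaults describe a mid-sized benchmark: 400 proteins in 10 interaction
    communities of ~40 (dense complexes, p_within=0.6, sparse background
    p_between=0.004), 4 compartments, and a moderate sequence signal
    (motif_strength=0.6) — enough planted structure that the task is
    learnable but held-out negatives falling inside a community remain
    genuinely hard.
    """

    n_proteins: int = 400
    n_compartments: int = 4
    n_blocks: int = 10
    p_within: float = 0.6
    p_between: float = 0.004
    motif_strength: float = 0.6
    seq_length_range: tuple[int, int] = (50, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_between < self.p_within <= 1:
            raise ValueError("require 0 <= p_between < p_within <= 1")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if self.n_compartments < 2:
            raise ValueError("n_compartments must be >= 2")
        lo, hi = self.seq_length_range
        if lo < 50 or hi < lo:
            raise ValueError("sequence lengths must be >= 50 (filter floor) "
                             "and the range non-empty")
        if not 0 <= self.motif_strength <= 1:
            raise ValueError("motif_strength must lie in [0, 1]")


def _block_class_distributions(n_blocks: int, motif_strength: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-block distributions over the 7 residue classes.

    Each block mixes the uniform distribution with a block-specific
    Dirichlet(0.5) signature; motif_strength=0 collapses every block to the
    uniform distribution (no sequence signal).
    """
    uniform = np.full(7, 1.0 / 7.0)
    signatures = rng.dirichlet(np.full(7, 0.5), size=n_blocks)
    return (1.0 - motif_strength) * uniform + motif_strength * signatures


def _sample_sequence(length: int, class_dist: np.ndarray,
                     rng: np.random.Generator) -> str:
    classes = rng.choice(7, size=length, p=class_dist)
    return "".join(_CLASS_RESIDUES[c][rng.integers(len(_CLASS_RESIDUES[c]))]
                   for c in classes)


def generate_dataset(spec: SyntheticSpec,
                     ) -> tuple[list[ProteinRecord], EdgeList]:
    """Generate proteins, positive edges and high-negative edges.

    Blocks and compartments are assigned uniformly and independently.
    Positive edges are Bernoulli(p_within) inside a block and
    Bernoulli(p_between) across blocks.  High-negative pairs are sampled
    cross-compartment (never duplicating a positive) to match the positive
    count.  Deterministic given ``spec.seed``.
    """
    n = spec.n_proteins
    rng = np.random.default_rng(derive_seed(spec.seed, "synthetic-structure"))
    blocks = rng.integers(spec.n_blocks, size=n)
    comps = rng.integers(spec.n_compartments, size=n)
    width = len(str(n))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    # sequences
    seq_rng = np.random.default_rng(derive_seed(spec.seed, "synthetic-seq"))
    dists = _block_class_distributions(spec.n_blocks, spec.motif_strength,
                                       seq_rng)
    lo, hi = spec.seq_length_range
    records = []
    for i in range(n):
        length = int(seq_rng.integers(lo, hi + 1))
        seq = _sample_sequence(length, dists[blocks[i]], seq_rng)
        records.append(ProteinRecord(
            id=ids[i], sequence=seq,
            annotations={"species": "synthetic",
                         "localizations": [f"compartment_{comps[i]}"],
                         "is_fragment": False,
                         "block": int(blocks[i])}))

    # positive edges
    edge_rng = np.random.default_rng(derive_seed(spec.seed, "synthetic-edges"))
    iu, ju = np.triu_indices(n, k=1)
    same_block = blocks[iu] == blocks[ju]
    p = np.where(same_block, spec.p_within, spec.p_between)
    hit = edge_rng.random(p.size) < p
    positives = EdgeList([(ids[int(a)], ids[int(b)], POSITIVE)
                          for a, b in zip(iu[hit], ju[hit])])

    n_neg = len(positives)
    if n_neg == 0:
        raise ValueError("spec produced no positive edges; raise p_within")
    attainable = count_cross_location_pairs(records, positives)
    if attainable < n_neg:
        raise ValueError(f"spec infeasible: need {n_neg} negative pairs but "
                         f"only {attainable} cross-compartment pairs exist")
    negatives = generate_negative_pairs(records, n_neg, positives,
                                        seed=derive_seed(spec.seed,
                                                         "synthetic-negatives"))
    edges = EdgeList(list(positives) + list(negatives))
    return records, edges


# ---------------------------------------------------------------------------
# Worked fixture — small enough to verify by hand


#: Expected conjoint-triad counts of fixture protein F1, computed by hand:
#: "AGV" * 20 is 60 residues all in class 1, so the 58 windows all hit triad
#: (1,1,1) at flat index 0.
FIXTURE_F1_CT = {0: 58}

_FIXTURE_SEQS = {
    # F1: pure class-1 residues (A, G, V)
    "F1": "AGV" * 20,
    # F2: alternating class 1 / class 5
    "F2": "ARKG" * 15,
    "F3": "ILFP" * 15,
    "F4": "YMTSYMTS" * 8,
    "F5": "HNQWDE" * 10,
    "F6": "CACA" * 15,
    "F7": "MKVLDE" * 10,
    "F8": "GGHHRRDD" * 8,
}

_FIXTURE_LOCS = {"F1": "nucleus", "F2": "nucleus",
                 "F3": "cytoplasm", "F4": "cytoplasm",
                 "F5": "membrane", "F6": "membrane",
                 "F7": "mitochondrion", "F8": "mitochondrion"}

_FIXTURE_POSITIVES = [("F1", "F2"), ("F3", "F4"), ("F5", "F6"),
                      ("F7", "F8"), ("F1", "F3"), ("F5", "F7")]

_FIXTURE_NEGATIVES = [("F1", "F4"), ("F2", "F5"), ("F3", "F6"),
                      ("F4", "F7"), ("F6", "F8"), ("F2", "F7")]


def make_worked_fixture() -> tuple[list[ProteinRecord], EdgeList]:
    """Hard-coded 8-protein dataset with hand-verifiable structure.

    Six positive and six high-negative pairs; every negative pair crosses
    compartments; every sequence is at least 50 canonical residues, so the
    whole fixture passes the dataset filters.  ``FIXTURE_F1_CT`` holds the
    hand-computed conjoint-triad counts of protein F1.
    """
    records = [ProteinRecord(id=pid, sequence=seq,
                             annotations={"species": "synthetic",
                                          "localizations": [_FIXTURE_LOCS[pid]],
                                          "is_fragment": False})
               for pid, seq in _FIXTURE_SEQS.items()]
    edges = EdgeList([(a, b, POSITIVE) for a, b in _FIXTURE_POSITIVES]
                     + [(a, b, HIGH_NEGATIVE) for a, b in _FIXTURE_NEGATIVES])
    return records, edges
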