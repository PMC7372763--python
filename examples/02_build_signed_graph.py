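"""The signed adjacency matrix and the high-confidence mask.

Observed interactions get +1, high-confidence non-interactions (pairs of
proteins confined to different subcellular compartments) get −1, all other
pairs stay 0 and are excluded from the reconstruction loss.  Self-loops
are added as the identity.
"""

from svgae import (build_signed_adjacency, filter_negative_candidates,
                   generate_negative_pairs, make_worked_fixture)

records, edges = make_worked_fixture()
print("fixture:", len(records), "proteins,",
      len(edges.positives), "positive /", len(edges.negatives),
      "high-negative pairs")

# the negative-candidate filters (species tag, unambiguous unique
# localization, no fragments/short sequences, canonical residues only)
kept = filter_negative_candidates(records, species="synthetic")
print("negative-candidate filter kept:", [r.id for r in kept])

# fresh negatives: random cross-compartment pairs that are not positives
fresh = generate_negative_pairs(kept, n_pairs=4, positives=edges, seed=0)
print("sampled cross-compartment negatives:", sorted(fresh.keys()))

adj = build_signed_adjacency([r.id for r in records], edges)
print("\nsigned adjacency (+1 interaction, -1 high-confidence negative):")
print("     " + " ".join(f"{pid:>3}" for pid in adj.node_index))
for pid, row in zip(adj.node_index, adj.matrix.astype(int)):
    print(f"{pid:>4} " + " ".join(f"{v:>3}" for v in row))
print(f"\nconfidence mask covers {int(adj.confidence_mask.sum())} cells "
      "(each pair appears twice: the matrix is symmetric)")
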