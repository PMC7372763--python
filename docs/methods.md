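# Methods

## Model

The package predicts protein–protein interactions from two coupled
sources: conjoint-triad (CT) sequence composition and the topology of a
*signed* interaction graph.

**Sequence coding.** Residues map to 7 classes grouped by side-chain
dipole and volume; ordered triads of classes are counted with a sliding
window of width 3, giving 7³ = 343 features per protein. The triad
(a, b, c) lives at flat index (a−1)·49 + (b−1)·7 + (c−1); the convention
is arbitrary but fixed, so serialized feature matrices are stable. Raw
counts of a length-L sequence sum to L − 2. By default rows are
normalized to frequencies (divide by the row sum) before entering the
encoder: counts scale linearly with sequence length, and bounded inputs
keep the un-normalized "raw" propagation mode numerically tame. Raw
counts remain available (`normalize=False`). One residue-naming wrinkle:
the class-4 group is His/Asn/Gln/Trp; a common typography renders
tryptophan as "Tpr", which is not an amino-acid code — it is treated as
Trp (W) here.

**Signed adjacency.** Observed interactions are +1; high-confidence
negatives −1; all else 0; the diagonal is +1 (self-loops via identity
addition). The confidence mask A* is exactly the off-diagonal ±1 cells:
uncertain cells are treated as noise and excluded from the loss, not
reconstructed toward 0. High-confidence negatives come from the classic
compartment argument — two proteins confined to different subcellular
locations do not interact — behind five filters (species tag;
no ambiguity qualifiers like "potential"/"probable"; exactly one
localization; no fragments and ≥ 50 residues; canonical residues only).
Records lacking annotations are excluded from the negative-sampling pool
but stay in the graph as nodes.

**Encoder / decoder.** Two-layer GCN with shared first-layer weights
produces per-node Gaussian posteriors (defaults: 96 hidden units, 48
latent dimensions). Each layer applies one propagation (two total).
The propagation matrix defaults to the signed adjacency itself ("raw"
mode, faithful to the formulation this package implements); a
symmetrically normalized variant D^{−1/2} A D^{−1/2} with D built from
|A| row sums is available (`propagation_mode="signed_sym_norm"`) and is
exercised by the same oracle tests. The decoder is σ(zᵢᵀzⱼ). Since a
sigmoid cannot produce −1, the −1 cells are reconstructed toward target
0; the sign itself acts in the propagation matrix (repulsion during
message passing) and in defining the mask.

**Loss and training.** Mean binary cross-entropy over masked cells, with
positive cells up-weighted by #masked/(2·#positives) ("balanced", exactly
1 when classes are balanced, which the generator guarantees; configurable),
plus the closed-form KL to a standard-normal prior divided by N (per-node
scaling, following the variational graph auto-encoder lineage). Full-batch
Adam, lr 0.005, 50 epochs, Glorot-uniform init, reparameterization trick
with one noise draw per epoch. log σ is clipped to ±10 so the KL's
exp(2·log σ) cannot overflow under raw propagation; the clip's subgradient
is zero outside the bounds. Encoder dropout exists but defaults to 0 —
dropout belongs to the classifier stage. All gradients are analytic
NumPy; a divergent (non-finite) loss raises with the last finite report
attached.

**Inference embeddings.** The posterior mean μ (not a sample) feeds the
classifier, making downstream predictions deterministic. Sampled latents
are still recorded with their seed for reproducibility.

**Classifier.** 2P → 128 → 64 → 32 → 2 MLP, ReLU, dropout 0.5 on hidden
activations, softmax head, two-class cross-entropy, Adam lr 0.005,
50 epochs, full batch. Concatenation is order-dependent while interaction
is not, so each labelled pair trains in both orders and test pairs score
as the mean of both orders; a tie at the 0.5 threshold resolves positive.

## Evaluation protocol

Labelled pairs split 80/20, stratified by label; five independent repeats.
The encoder trains on an adjacency built from *training pairs only* —
held-out pairs are absent from both the matrix and the mask, since an
encoder that has seen test edges leaks the answer. Within the training
pairs, stratified 5-fold cross-validation selects the classifier
checkpoint (train on 4/5, keep the fold-model with the best validation
accuracy); reported numbers always come from the untouched 20% hold-out,
as mean ± sd over the five repeats (sd over repeats, not folds).

The coverage sweep keeps, per protein and per edge label independently,
⌈coverage · degree⌉ incident edges chosen at random (so every protein with
any edge keeps at least one — even at coverage 0.1 no node is stranded);
an edge survives if either endpoint drew it. Each level retrains from
scratch against one fixed test split. The sign ablation reruns the
identical pipeline with every −1 flattened to +1, same mask and same
derived seeds, so the arms differ only in adjacency sign content.

Undefined metrics (zero denominator) are reported as flagged-undefined
rather than coerced to 0.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` plants three structures: interaction communities
(within-block edge probability p_within, cross-block p_between),
compartment labels (uniform, independent of blocks) that gate negative
sampling, and block-specific residue-class distributions (uniform mixed
with a per-block Dirichlet(0.5) signature, mixing weight
`motif_strength`; residues drawn uniformly within class).

Defaults — 400 proteins, 10 blocks, p_within 0.6, p_between 0.004,
4 compartments, motif_strength 0.6, lengths 50–150 — were chosen from the
task's information structure: held-out negatives are random
cross-compartment pairs, so a negative falling *inside* one interaction
block is structurally indistinguishable from a held-out positive; with
K blocks that confusion affects ≈ 1/K of negatives, putting the accuracy
ceiling near 0.93 for K = 10. Hold-out accuracy ≈ 0.9 therefore means
near-ceiling recovery, not a soft target. Blocks are decoupled from
compartments precisely so compartment leakage cannot solve the task.

What passing these tests does **not** show: real PPI networks have
heavy-tailed degree distributions, overlapping complexes, assay-specific
false positives and sequence homology between interactors — none of which
the generator models. Results on planted data demonstrate that the
machinery recovers the structure it is designed for, not field
performance on curated interactome databases.

## Numerical and design choices

- Seeds: one master seed; every stage draws its seed through
  `derive_seed(master, *tags)` (SeedSequence over the master plus CRC32 of
  stage tags), documented and platform-stable; derived seeds < 2³¹.
- Negative-pair sampling is uniform by rejection with an exact
  feasibility count up front (compartment-size arithmetic minus
  cross-compartment positives); if the pool nearly exhausts, it falls
  back to explicit enumeration, preserving uniformity and determinism.
- Conflicting duplicate edges (same pair, both labels) are a hard error,
  never a silent precedence.
- Sequences shorter than 3 residues encode to a zero vector with a
  warning rather than an error; dataset filters (≥ 50 residues) remove
  them upstream in any real run.
- Stratified splitting and k-fold assignment use scikit-learn
  (`train_test_split`, `StratifiedKFold`) behind the `split_edges`
  surface.
- Problem sizes in tests: unit and property tests run on graphs of
  20–120 nodes, the end-to-end checks on the 400-protein default; the
  feature-informativeness property is checked on a sparse graph
  (p_within 0.15) because on dense planted graphs topology alone
  saturates link prediction and the sequence contribution is invisible.

## Known limitations

- Full-batch dense linear algebra: fine into the low thousands of nodes,
  not built for genome-scale graphs (no minibatching or neighbor
  sampling).
- Edge confidence is ternary (+1/0/−1); graded confidence weights are not
  supported.
- The decoder's raw probabilities separate classes only modestly; the
  feedforward classifier is the intended final predictor.
- The compartment argument for negatives is an assumption, not ground
  truth; in real data some cross-compartment pairs do interact.
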