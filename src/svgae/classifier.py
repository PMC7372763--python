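"""Feedforward interaction classifier on concatenated embedding pairs.

A small multilayer perceptron (2P -> 128 -> 64 -> 32 -> 2) with ReLU hidden
activations, dropout 0.5 during training and a two-unit softmax head, trained
full-batch with Adam on two-class cross-entropy.  Because concatenation is
order-dependent while interaction is not, training pairs are presented in
both orders and test pairs are scored as the mean of both orders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .graph import EdgeList, POSITIVE
from .model import Adam, EmbeddingSet, glorot_uniform, relu

__all__ = ["PairFeature", "ClassifierWeights", "pair_features",
           "train_classifier", "predict_pairs", "score_interactions"]


@dataclass
class PairFeature:
    """Concatenated embeddings [z_a || z_b] for one candidate pair."""

    vector: np.ndarray
    pair: tuple[str, str]
    label: int | None = None  # 1 interacting, 0 not


@dataclass
class ClassifierWeights:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout_rate: float

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def copy(self) -> "ClassifierWeights":
        return ClassifierWeights([w.copy() for w in self.weights],
                                 [b.copy() for b in self.biases],
                                 self.dropout_rate)


def pair_features(embeddings: EmbeddingSet, pairs: EdgeList | list,
                  symmetrize: bool = True) -> list[PairFeature]:
    """Build classifier inputs from deterministic (mu) embeddings.

    Labels map +1 -> 1 and −1 -> 0.  With ``symmetrize`` each labelled pair
    yields both concatenation orders with the same label.
    """
    index = {pid: i for i, pid in enumerate(embeddings.ids)}
    out: list[PairFeature] = []
    for a, b, lab in pairs:
        try:
            ia, ib = index[a], index[b]
        except KeyError as exc:
            raise ValueError(f"pair references unknown protein id {exc}") from None
        label = 1 if lab == POSITIVE else 0
        za, zb = embeddings.mu[ia], embeddings.mu[ib]
        out.append(PairFeature(np.concatenate([za, zb]), (a, b), label))
        if symmetrize:
            out.append(PairFeature(np.concatenate([zb, za]), (b, a), label))
    return out


def init_classifier(input_dim: int, layers: tuple[int, ...], dropout: float,
                    seed: int) -> ClassifierWeights:
    rng = np.random.default_rng(seed)
    sizes = [input_dim, *layers, 2]
    ws = [glorot_uniform(rng, sizes[i], sizes[i + 1])
          for i in range(len(sizes) - 1)]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return ClassifierWeights(weights=ws, biases=bs, dropout_rate=dropout)


def _forward(w: ClassifierWeights, X: np.ndarray, training: bool,
             rng: np.random.Generator | None):
    """Forward pass; returns (softmax probs, cached activations, dropout masks)."""
    acts = [X]
    masks: list[np.ndarray | None] = []
    h = X
    n_layers = len(w.weights)
    for l in range(n_layers - 1):
        h = relu(h @ w.weights[l] + w.biases[l])
        if training and w.dropout_rate > 0:
            keep = (rng.random(h.shape) >= w.dropout_rate)
            h = h * keep / (1.0 - w.dropout_rate)
            masks.append(keep)
        else:
            masks.append(None)
        acts.append(h)
    logits = h @ w.weights[-1] + w.biases[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    return probs, acts, masks


def train_classifier(features: list[PairFeature], config: RunConfig,
                     ) -> ClassifierWeights:
    """Train the MLP on labelled pair features (full-batch Adam).

    Deterministic given ``config.seed``; ``classifier_epochs=0`` returns the
    freshly initialized weights.  Raises if only one class is present.
    """
    labels = [f.label for f in features]
    if any(l is None for l in labels):
        raise ValueError("all training pair features must carry a label")
    y = np.array(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both interacting and "
                         "non-interacting pairs")
    X = np.vstack([f.vector for f in features])
    w = init_classifier(X.shape[1], config.classifier_layers,
                        config.classifier_dropout,
                        seed=config.stage_seed("classifier-init"))
    drop_rng = np.random.default_rng(config.stage_seed("classifier-dropout"))
    opt = Adam(w.weights + w.biases, lr=config.classifier_lr)
    n = X.shape[0]
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y] = 1.0

    for _epoch in range(config.classifier_epochs):
        probs, acts, masks = _forward(w, X, training=True, rng=drop_rng)
        # mean cross-entropy gradient at the softmax logits
        g = (probs - onehot) / n
        grads_w: list[np.ndarray] = [np.empty(0)] * len(w.weights)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(w.biases)
        for l in range(len(w.weights) - 1, -1, -1):
            grads_w[l] = acts[l].T @ g
            grads_b[l] = g.sum(axis=0)
            if l > 0:
                g = g @ w.weights[l].T
                if masks[l - 1] is not None:
                    g = g * masks[l - 1] / (1.0 - w.dropout_rate)
                g = g * (acts[l] > 0)
        opt.step(grads_w + grads_b)
    return w


def predict_pairs(weights: ClassifierWeights, features: list[PairFeature],
                  threshold: float = 0.5,
                  ) -> list[tuple[tuple[str, str], float, int]]:
    """Score pair features with dropout disabled.

    Returns (pair, interaction probability, predicted label); the label is
    1 iff probability >= threshold (ties at the threshold are positive).
    """
    if not features:
        return []
    X = np.vstack([f.vector for f in features])
    if X.shape[1] != weights.input_dim:
        raise ValueError(f"feature length {X.shape[1]} does not match "
                         f"classifier input {weights.input_dim}")
    probs, _, _ = _forward(weights, X, training=False, rng=None)
    p_pos = probs[:, 1]
    return [(f.pair, float(p), int(p >= threshold))
            for f, p in zip(features, p_pos)]


def score_interactions(weights: ClassifierWeights, embeddings: EmbeddingSet,
                       pairs: EdgeList | list, symmetrize: bool = True,
                       threshold: float = 0.5,
                       ) -> list[tuple[tuple[str, str], float, int]]:
    """Score candidate pairs, averaging both concatenation orders.

    This is the inference counterpart of the symmetrized training scheme:
    score(a, b) == score(b, a) by construction.
    """
    feats_fwd = pair_features(embeddings, pairs, symmetrize=False)
    probs_fwd = [p for _, p, _ in predict_pairs(weights, feats_fwd, threshold)]
    if symmetrize:
        rev = [(b, a, lab) for a, b, lab in pairs]
        feats_rev = pair_features(embeddings, rev, symmetrize=False)
        probs_rev = [p for _, p, _ in predict_pairs(weights, feats_rev, threshold)]
        probs = [(f + r) / 2.0 for f, r in zip(probs_fwd, probs_rev)]
    else:
        probs = probs_fwd
    return [((a, b), float(p), int(p >= threshold))
            for (a, b, _), p in zip(pairs, probs)]
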