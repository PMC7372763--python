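"""Signed variational graph auto-encoder: encoder, decoder, loss, training.

The encoder is a two-layer graph convolutional network producing a diagonal
Gaussian posterior per node,

    hidden    = ReLU(P X W0)
    mu        = P hidden W1_mu
    log_sigma = P hidden W1_sigma

where P is the propagation matrix derived from the signed adjacency A
(either A itself or its symmetrically normalized form D^{-1/2} A D^{-1/2}
with D the diagonal of |A| row sums).  Latents are sampled with the
reparameterization trick, z = mu + sigma * eps.  The decoder scores each
pair by the logistic sigmoid of the latent inner product, sigma(z_i^T z_j).

Training maximizes the evidence lower bound restricted to the
high-confidence cells A*: binary cross-entropy toward target 1 on +1 cells
and target 0 on −1 cells, minus the KL divergence of the posterior from a
standard-normal prior.  Optimization is full-batch Adam with Glorot-uniform
initialization; everything is plain NumPy with analytic gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .graph import SignedAdjacency

logger = logging.getLogger(__name__)

LOG_SIGMA_CLIP = 10.0  # |log sigma| bound; keeps exp() finite under raw propagation


@dataclass
class PropagationMatrix:
    """Dense propagation operator derived from a signed adjacency."""

    matrix: np.ndarray
    mode: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_propagation(adj: SignedAdjacency, mode: str = "raw") -> PropagationMatrix:
    """Build the GCN propagation matrix.

    ``raw`` uses the signed adjacency exactly as written (unit diagonal
    included).  ``signed_sym_norm`` applies D^{-1/2} A D^{-1/2} where D is
    the diagonal matrix of |A| row sums, the signed analogue of symmetric
    GCN normalization.
    """
    A = np.asarray(adj.matrix, dtype=np.float64)
    if mode == "raw":
        return PropagationMatrix(matrix=A.copy(), mode=mode)
    if mode == "signed_sym_norm":
        d = np.abs(A).sum(axis=1)
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
        return PropagationMatrix(matrix=dinv[:, None] * A * dinv[None, :],
                                 mode=mode)
    raise ValueError(f"unknown propagation mode '{mode}'")


@dataclass
class EncoderWeights:
    w0: np.ndarray        # R x H1, shared between the mu and sigma branches
    w1_mu: np.ndarray     # H1 x P
    w1_sigma: np.ndarray  # H1 x P

    def copy(self) -> "EncoderWeights":
        return EncoderWeights(self.w0.copy(), self.w1_mu.copy(),
                              self.w1_sigma.copy())


@dataclass
class EmbeddingSet:
    """Per-protein posterior mean, log-std and one sampled latent."""

    ids: list[str]
    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray
    seed: int

    def vector(self, pid: str) -> np.ndarray:
        """Deterministic embedding (posterior mean) for one protein."""
        return self.mu[self.ids.index(pid)]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        p = self.mu.shape[1]
        df = pd.DataFrame(self.mu, index=pd.Index(self.ids, name="id"),
                          columns=[f"e{k}" for k in range(p)])
        df.to_csv(path, sep="\t")


@dataclass
class LossReport:
    total: float
    reconstruction: float
    kl: float
    epoch: int


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder_weights(n_features: int, hidden1: int, embed_dim: int,
                         seed: int) -> EncoderWeights:
    rng = np.random.default_rng(seed)
    return EncoderWeights(w0=glorot_uniform(rng, n_features, hidden1),
                          w1_mu=glorot_uniform(rng, hidden1, embed_dim),
                          w1_sigma=glorot_uniform(rng, hidden1, embed_dim))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


def gcn_layer(X: np.ndarray, p_mat: PropagationMatrix, W: np.ndarray,
              activation: str = "relu") -> np.ndarray:
    """One graph convolution: activation(P @ X @ W)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != p_mat.n:
        raise ValueError(f"propagation matrix is {p_mat.n}x{p_mat.n} but X has "
                         f"{X.shape[0]} rows")
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but W expects {W.shape[0]}")
    out = p_mat.matrix @ X @ W
    if activation == "relu":
        return relu(out)
    if activation == "identity":
        return out
    raise ValueError(f"unknown activation '{activation}'")


def encode(X: np.ndarray, p_mat: PropagationMatrix, w: EncoderWeights,
           dropout_rate: float = 0.0, training: bool = False,
           rng: np.random.Generator | None = None,
           ) -> tuple[np.ndarray, np.ndarray]:
    """Two-layer GCN variational encoder; returns (mu, log_sigma).

    The second layer is linear; both output branches share the first-layer
    weights.  Dropout (inverted scaling) acts on the hidden layer only when
    ``training`` is set.
    """
    hidden = gcn_layer(X, p_mat, w.w0, activation="relu")
    if training and dropout_rate > 0:
        if rng is None:
            raise ValueError("dropout during training requires an rng")
        keep = (rng.random(hidden.shape) >= dropout_rate)
        hidden = hidden * keep / (1.0 - dropout_rate)
    mu = p_mat.matrix @ hidden @ w.w1_mu
    log_sigma = np.clip(p_mat.matrix @ hidden @ w.w1_sigma,
                        -LOG_SIGMA_CLIP, LOG_SIGMA_CLIP)
    if not (np.isfinite(mu).all() and np.isfinite(log_sigma).all()):
        raise FloatingPointError("non-finite encoder output")
    return mu, log_sigma


def reparameterize(mu: np.ndarray, log_sigma: np.ndarray,
                   seed: int) -> np.ndarray:
    """Sample z = mu + exp(log_sigma) * eps with eps ~ N(0, I) under seed."""
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma must have identical shapes")
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    return mu + np.exp(log_sigma) * eps


def decode_pair(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """Interaction probability sigma(z_i^T z_j) of two latent vectors."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape:
        raise ValueError("latent vectors must have equal length")
    return float(_sigmoid(z_i @ z_j))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def kl_term(mu: np.ndarray, log_sigma: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag(sigma^2)) || N(0, I) ), summed over entries.

    KL = 1/2 * sum( sigma^2 + mu^2 - 1 - 2 log sigma ); zero exactly when the
    posterior equals the prior, non-negative always.
    """
    mu = np.asarray(mu, dtype=float)
    log_sigma = np.asarray(log_sigma, dtype=float)
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma must have identical shapes")
    return float(0.5 * np.sum(np.exp(2.0 * log_sigma) + mu ** 2
                              - 1.0 - 2.0 * log_sigma))


def _resolve_pos_weight(pos_weight, adjacency: SignedAdjacency) -> float:
    if pos_weight == "balanced":
        mask = adjacency.confidence_mask
        n_pos = int((adjacency.matrix[mask] > 0).sum())
        n_masked = int(mask.sum())
        if n_pos == 0:
            return 1.0
        return n_masked / (2.0 * n_pos)
    return float(pos_weight)


def reconstruction_term(Z: np.ndarray, adjacency: SignedAdjacency,
                        pos_weight: str | float = 1.0) -> float:
    """Masked reconstruction loss over the high-confidence cells A*.

    Mean binary cross-entropy of sigma(z_i^T z_j) against target 1 on +1
    cells and target 0 on −1 cells; cells outside the confidence mask
    contribute nothing.  ``pos_weight`` up-weights positive cells
    ("balanced" uses #masked / (2 #positive)).
    """
    mask = adjacency.confidence_mask
    m = int(mask.sum())
    if m == 0:
        raise ValueError("confidence mask is empty: nothing to reconstruct")
    if Z.shape[0] != adjacency.n:
        raise ValueError("Z row count must equal the number of nodes")
    w_pos = _resolve_pos_weight(pos_weight, adjacency)
    logits = (Z @ Z.T)[mask]
    targets = (adjacency.matrix[mask] > 0).astype(float)
    weights = np.where(targets > 0, w_pos, 1.0)
    # numerically stable BCE-with-logits
    bce = np.maximum(logits, 0.0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    return float(np.sum(weights * bce) / m)


def _kl_factor(kl_scale, n: int) -> float:
    return 1.0 / n if kl_scale == "per_node" else float(kl_scale)


def elbo_loss(Z: np.ndarray, mu: np.ndarray, log_sigma: np.ndarray,
              adjacency: SignedAdjacency, config: RunConfig,
              epoch: int = 0) -> LossReport:
    rec = reconstruction_term(Z, adjacency, pos_weight=config.pos_weight)
    kl = _kl_factor(config.kl_scale, adjacency.n) * kl_term(mu, log_sigma)
    return LossReport(total=rec + kl, reconstruction=rec, kl=kl, epoch=epoch)


class Adam:
    """Standard Adam updates for a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_svgae(X: np.ndarray, adjacency: SignedAdjacency, config: RunConfig,
                ) -> tuple[EncoderWeights, EmbeddingSet, list[LossReport]]:
    """Full-batch training of the signed variational graph auto-encoder.

    Minimizes the negative evidence lower bound (masked reconstruction loss
    plus per-node KL) with Adam.  All randomness — weight initialization,
    the per-epoch reparameterization noise, dropout — derives from
    ``config.seed``.  Returns the trained weights, an :class:`EmbeddingSet`
    whose deterministic ``mu`` is used downstream, and per-epoch losses.
    """
    if int(adjacency.confidence_mask.sum()) == 0:
        raise ValueError("confidence mask is empty: nothing to train on")
    X = np.asarray(X, dtype=np.float64)
    n, r = X.shape
    if n != adjacency.n:
        raise ValueError("feature matrix rows must match adjacency size")

    weights = init_encoder_weights(r, config.hidden1, config.embed_dim,
                                   seed=config.stage_seed("svgae-init"))
    p_mat = build_propagation(adjacency, config.propagation_mode)
    P = p_mat.matrix
    PX = P @ X  # constant across epochs
    mask = adjacency.confidence_mask
    m_count = int(mask.sum())
    targets = (adjacency.matrix > 0).astype(float)
    w_pos = _resolve_pos_weight(config.pos_weight, adjacency)
    cell_w = np.where(mask, np.where(targets > 0, w_pos, 1.0), 0.0)
    kl_fac = _kl_factor(config.kl_scale, n)

    noise_rng = np.random.default_rng(config.stage_seed("svgae-noise"))
    drop_rng = np.random.default_rng(config.stage_seed("svgae-dropout"))
    opt = Adam([weights.w0, weights.w1_mu, weights.w1_sigma], lr=config.lr)

    reports: list[LossReport] = []
    last_finite: LossReport | None = None
    for epoch in range(1, config.epochs + 1):
        # ---- forward
        pre0 = PX @ weights.w0
        h = relu(pre0)
        if config.encoder_dropout > 0:
            keep = (drop_rng.random(h.shape) >= config.encoder_dropout)
            hd = h * keep / (1.0 - config.encoder_dropout)
        else:
            keep = None
            hd = h
        Ph = P @ hd
        mu = Ph @ weights.w1_mu
        ls_raw = Ph @ weights.w1_sigma
        ls = np.clip(ls_raw, -LOG_SIGMA_CLIP, LOG_SIGMA_CLIP)
        eps = noise_rng.standard_normal(mu.shape)
        sig = np.exp(ls)
        Z = mu + sig * eps

        logits = Z @ Z.T
        probs = _sigmoid(logits)
        bce = np.maximum(logits, 0.0) - logits * targets + \
            np.log1p(np.exp(-np.abs(logits)))
        rec = float(np.sum(cell_w * np.where(mask, bce, 0.0)) / m_count)
        kl = kl_fac * kl_term(mu, ls)
        total = rec + kl
        if not np.isfinite(total):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}; last finite loss: "
                f"{last_finite}")
        last_finite = LossReport(total=total, reconstruction=rec, kl=kl,
                                 epoch=epoch)
        reports.append(last_finite)

        # ---- backward
        g_logits = cell_w * np.where(mask, probs - targets, 0.0) / m_count
        dZ = (g_logits + g_logits.T) @ Z
        dmu = dZ + kl_fac * mu
        dls = dZ * sig * eps + kl_fac * (np.exp(2.0 * ls) - 1.0)
        dls[np.abs(ls_raw) > LOG_SIGMA_CLIP] = 0.0  # clip subgradient
        dW1m = Ph.T @ dmu
        dW1s = Ph.T @ dls
        dhd = P.T @ (dmu @ weights.w1_mu.T + dls @ weights.w1_sigma.T)
        if keep is not None:
            dhd = dhd * keep / (1.0 - config.encoder_dropout)
        dpre0 = dhd * (pre0 > 0)
        dW0 = PX.T @ dpre0
        opt.step([dW0, dW1m, dW1s])

        if epoch == 1 or epoch % 10 == 0:
            logger.info("epoch %3d  total %.4f  recon %.4f  kl %.4f",
                        epoch, total, rec, kl)

    mu, ls = encode(X, p_mat, weights, training=False)
    sample_seed = config.stage_seed("svgae-sample")
    z = reparameterize(mu, ls, seed=sample_seed)
    embeddings = EmbeddingSet(ids=list(adjacency.node_index), mu=mu,
                              log_sigma=ls, z=z, seed=sample_seed)
    return weights, embeddings, reports


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(path: str | Path, weights: EncoderWeights,
                    config: RunConfig) -> None:
    """Serialize encoder weights + config to a portable .npz checkpoint."""
    import json

    np.savez(path, w0=weights.w0, w1_mu=weights.w1_mu,
             w1_sigma=weights.w1_sigma,
             config=np.frombuffer(json.dumps(config.to_dict()).encode(),
                                  dtype=np.uint8))


def load_checkpoint(path: str | Path) -> tuple[EncoderWeights, RunConfig]:
    import json

    with np.load(path) as data:
        weights = EncoderWeights(w0=data["w0"], w1_mu=data["w1_mu"],
                                 w1_sigma=data["w1_sigma"])
        cfg_dict = json.loads(bytes(data["config"]).decode())
    cfg_dict["classifier_layers"] = tuple(cfg_dict["classifier_layers"])
    return weights, RunConfig(**cfg_dict)
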