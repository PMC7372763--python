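"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected values by direct enumeration or simulation and
share no code paths with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

# Seven-class grouping retyped independently: class -> residues
ORACLE_GROUPS = {
    1: "AGV", 2: "ILFP", 3: "YMTS", 4: "HNQW", 5: "RK", 6: "DE", 7: "C",
}
ORACLE_CLASS = {aa: cls for cls, aas in ORACLE_GROUPS.items() for aa in aas}


def ct_counts_bruteforce(sequence: str) -> dict[int, int]:
    """Count triads by explicit window enumeration; flat index
    (a-1)*49 + (b-1)*7 + (c-1)."""
    counts: dict[int, int] = {}
    for i in range(len(sequence) - 2):
        a = ORACLE_CLASS[sequence[i]]
        b = ORACLE_CLASS[sequence[i + 1]]
        c = ORACLE_CLASS[sequence[i + 2]]
        idx = (a - 1) * 49 + (b - 1) * 7 + (c - 1)
        counts[idx] = counts.get(idx, 0) + 1
    return counts


def gcn_bruteforce(A: np.ndarray, X: np.ndarray, W: np.ndarray,
                   use_relu: bool) -> np.ndarray:
    """activation(A X W) via explicit Python loops."""
    n, f = X.shape
    g = W.shape[1]
    AX = np.zeros((n, f))
    for i in range(n):
        for j in range(n):
            for k in range(f):
                AX[i, k] += A[i, j] * X[j, k]
    out = np.zeros((n, g))
    for i in range(n):
        for k in range(f):
            for l in range(g):
                out[i, l] += AX[i, k] * W[k, l]
    if use_relu:
        for i in range(n):
            for l in range(g):
                if out[i, l] < 0:
                    out[i, l] = 0.0
    return out


def encoder_bruteforce(A: np.ndarray, X: np.ndarray, W0: np.ndarray,
                       W1m: np.ndarray, W1s: np.ndarray,
                       clip: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Two-layer composition: hidden = relu(A X W0); mu = A hidden W1m;
    log_sigma = clip(A hidden W1s)."""
    hidden = gcn_bruteforce(A, X, W0, use_relu=True)
    mu = gcn_bruteforce(A, hidden, W1m, use_relu=False)
    ls = np.clip(gcn_bruteforce(A, hidden, W1s, use_relu=False), -clip, clip)
    return mu, ls


def kl_montecarlo(mu: np.ndarray, log_sigma: np.ndarray, n_samples: int,
                  seed: int) -> float:
    """Monte-Carlo KL( N(mu, sigma^2) || N(0, 1) ) summed over entries:
    E_q[log q(x) - log p(x)] estimated by sampling from q."""
    rng = np.random.default_rng(seed)
    sigma = np.exp(log_sigma)
    total = 0.0
    for m, s in zip(mu.ravel(), sigma.ravel()):
        x = rng.normal(m, s, size=n_samples)
        log_q = -0.5 * math.log(2 * math.pi) - math.log(s) \
            - 0.5 * ((x - m) / s) ** 2
        log_p = -0.5 * math.log(2 * math.pi) - 0.5 * x ** 2
        total += float(np.mean(log_q - log_p))
    return total


def metrics_from_labels(truth, pred) -> dict[str, float | None]:
    """Recompute the five metrics directly from label vectors."""
    tp = sum(1 for t, p in zip(truth, pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(truth, pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(truth, pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(truth, pred) if t == 1 and p == 0)
    out: dict[str, float | None] = {}
    out["accuracy"] = (tp + tn) / (tp + tn + fp + fn)
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else None
    out["specificity"] = tn / (tn + fp) if (tn + fp) else None
    out["precision"] = tp / (tp + fp) if (tp + fp) else None
    if out["sensitivity"] is None or out["precision"] is None or \
            (out["sensitivity"] + out["precision"]) == 0:
        out["f_score"] = None
    else:
        out["f_score"] = (2 * out["precision"] * out["sensitivity"]
                          / (out["precision"] + out["sensitivity"]))
    return out
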