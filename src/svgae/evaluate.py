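"""Evaluation: confusion metrics, repeated-split protocol, robustness sweeps.

Five classification metrics are reported: accuracy, sensitivity (recall),
specificity, precision and F-score (the harmonic mean of precision and
sensitivity).  The experimental protocol splits labelled pairs 80/20 five
times; each repeat trains the graph auto-encoder on the training graph only
(test pairs are removed from both the adjacency and the confidence mask, so
the encoder never sees held-out edges), selects a classifier checkpoint by
5-fold cross-validation inside the training pairs, and reports metrics on
the untouched 20% hold-out.  Aggregates are mean ± sd over the five repeats.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import (ClassifierWeights, pair_features, predict_pairs,
                         score_interactions, train_classifier)
from .config import RunConfig
from .graph import (EdgeList, SignedAdjacency, SplitSpec,
                    build_signed_adjacency, coverage_sample, split_edges)
from .model import EmbeddingSet, train_svgae
from .sequence import ProteinRecord, build_feature_matrix

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f_score")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Tally the 2x2 confusion table from binary label vectors."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"truth has {t.size} labels, predicted has {p.size}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(tp=int(((t == 1) & (p == 1)).sum()),
                           tn=int(((t == 0) & (p == 0)).sum()),
                           fp=int(((t == 0) & (p == 1)).sum()),
                           fn=int(((t == 1) & (p == 0)).sum()))


@dataclass
class MetricReport:
    """The five metrics; zero-denominator metrics are None and flagged."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f_score: float | None
    n: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def metrics(c: ConfusionCounts) -> MetricReport:
    """Compute accuracy, sensitivity, specificity, precision and F-score.

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F-score     = 2 * precision * sensitivity / (precision + sensitivity)

    Metrics whose denominator is zero are reported as None and listed in
    ``undefined`` rather than coerced to 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(c.tp + c.tn, c.total, "accuracy")
    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    if sens is None or prec is None or (prec + sens) == 0:
        undefined.append("f_score")
        f = None
    else:
        f = 2 * prec * sens / (prec + sens)
    return MetricReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        precision=prec, f_score=f, n=c.total,
                        undefined=tuple(undefined))


@dataclass
class AggregatedReport:
    """Mean ± sd of each metric over repeated hold-out evaluations."""

    mean: dict[str, float]
    sd: dict[str, float]
    per_repeat: list[MetricReport]

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "mean", "sd", "n"])
            for m in METRIC_NAMES:
                writer.writerow([m, self.mean.get(m, ""), self.sd.get(m, ""),
                                 self.n_repeats])


def aggregate(reports: list[MetricReport]) -> AggregatedReport:
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in METRIC_NAMES:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        if vals:
            mean[m] = float(np.mean(vals))
            sd[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return AggregatedReport(mean=mean, sd=sd, per_repeat=reports)


# ---------------------------------------------------------------------------
# End-to-end pipeline pieces


def _train_graph_adjacency(ids: Sequence[str], train_edges: EdgeList,
                           ) -> SignedAdjacency:
    """Adjacency built from training pairs only — held-out pairs are absent
    from both the matrix and the confidence mask (leak prevention)."""
    return build_signed_adjacency(ids, train_edges)


def train_pipeline(records: Sequence[ProteinRecord], train_edges: EdgeList,
                   config: RunConfig, adjacency: SignedAdjacency | None = None,
                   select_folds: list[int] | None = None,
                   ) -> tuple[EmbeddingSet, ClassifierWeights, list]:
    """Train encoder + classifier on the training pairs.

    When ``select_folds`` is given (per-train-pair fold ids), the classifier
    is trained once per fold on the complementary folds and the checkpoint
    with the best validation accuracy is kept; otherwise a single classifier
    is trained on all training pairs.
    """
    ids = [r.id for r in records]
    fm = build_feature_matrix(records, normalize=config.normalize_ct)
    if adjacency is None:
        adjacency = _train_graph_adjacency(ids, train_edges)
    _, embeddings, reports = train_svgae(fm.X, adjacency, config)

    pairs = list(train_edges)
    if select_folds is not None:
        folds = np.asarray(select_folds)
        best: tuple[float, ClassifierWeights] | None = None
        for f in sorted(set(folds.tolist())):
            fit_pairs = [p for p, fi in zip(pairs, folds) if fi != f]
            val_pairs = [p for p, fi in zip(pairs, folds) if fi == f]
            fold_cfg = replace(config, seed=config.stage_seed("fold", f))
            feats = pair_features(embeddings, fit_pairs,
                                  symmetrize=config.symmetrize)
            w = train_classifier(feats, fold_cfg)
            scored = score_interactions(w, embeddings, val_pairs,
                                        symmetrize=config.symmetrize,
                                        threshold=config.threshold)
            truth = [1 if lab == 1 else 0 for _, _, lab in val_pairs]
            pred = [lab for _, _, lab in scored]
            acc = metrics(confusion(truth, pred)).accuracy or 0.0
            if best is None or acc > best[0]:
                best = (acc, w)
        weights = best[1]
    else:
        feats = pair_features(embeddings, pairs, symmetrize=config.symmetrize)
        weights = train_classifier(feats, config)
    return embeddings, weights, reports


def evaluate_pairs(embeddings: EmbeddingSet, weights: ClassifierWeights,
                   test_edges: EdgeList, config: RunConfig) -> MetricReport:
    scored = score_interactions(weights, embeddings, list(test_edges),
                                symmetrize=config.symmetrize,
                                threshold=config.threshold)
    truth = [1 if lab == 1 else 0 for _, _, lab in test_edges]
    pred = [lab for _, _, lab in scored]
    return metrics(confusion(truth, pred))


def run_protocol(records: Sequence[ProteinRecord], edges: EdgeList,
                 config: RunConfig) -> AggregatedReport:
    """Repeated 80/20 hold-out protocol (default 5 repeats).

    Per repeat: stratified split, encoder training on the leak-masked graph,
    classifier checkpoint selection by stratified k-fold cross-validation
    within the training pairs, metrics on the hold-out pairs.
    """
    splits = split_edges(edges, test_fraction=config.test_fraction,
                         n_repeats=config.n_repeats, n_folds=config.n_folds,
                         seed=config.stage_seed("splits"))
    reports: list[MetricReport] = []
    for rep, split in enumerate(splits):
        rep_cfg = replace(config, seed=config.stage_seed("repeat", rep))
        try:
            embeddings, weights, _ = train_pipeline(
                records, split.train, rep_cfg,
                select_folds=split.fold_assignments)
            reports.append(evaluate_pairs(embeddings, weights, split.test,
                                          rep_cfg))
        except Exception as exc:
            raise RuntimeError(f"protocol repeat {rep} failed: {exc}") from exc
        logger.info("repeat %d: accuracy %.4f", rep, reports[-1].accuracy)
    return aggregate(reports)


def coverage_sweep(records: Sequence[ProteinRecord], edges: EdgeList,
                   coverages: Sequence[float], config: RunConfig,
                   out_csv: str | Path | None = None,
                   ) -> dict[float, MetricReport]:
    """Retrain end-to-end at each coverage level against a fixed test set.

    The training graph is sparsified per protein (``coverage_sample``)
    before encoder training; each level retrains from scratch.
    """
    split = split_edges(edges, test_fraction=config.test_fraction,
                        n_repeats=1, n_folds=config.n_folds,
                        seed=config.stage_seed("coverage-split"))[0]
    results: dict[float, MetricReport] = {}
    for cov in coverages:
        sampled = coverage_sample(split.train, cov,
                                  seed=config.stage_seed("coverage", cov))
        cov_cfg = replace(config, seed=config.stage_seed("coverage-run", cov))
        embeddings, weights, _ = train_pipeline(records, sampled, cov_cfg)
        results[cov] = evaluate_pairs(embeddings, weights, split.test, cov_cfg)
        logger.info("coverage %.2f: accuracy %s", cov, results[cov].accuracy)
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["coverage", *METRIC_NAMES, "n"])
            for cov, rep in results.items():
                writer.writerow([cov, *[rep.as_dict()[m] for m in METRIC_NAMES],
                                 rep.n])
    return results


def signed_ablation(records: Sequence[ProteinRecord], edges: EdgeList,
                    config: RunConfig) -> dict[str, MetricReport]:
    """Signed versus unsigned adjacency under identical seeds and mask.

    The unsigned arm replaces every −1 edge by +1 (so high-confidence
    non-interactions propagate and are reconstructed as if they were
    interactions) while keeping the confidence mask and all seeds fixed;
    only the sign content of the adjacency differs between arms.
    """
    split = split_edges(edges, test_fraction=config.test_fraction,
                        n_repeats=1, n_folds=config.n_folds,
                        seed=config.stage_seed("ablation-split"))[0]
    ids = [r.id for r in records]
    signed_adj = build_signed_adjacency(ids, split.train)
    unsigned_adj = signed_adj.unsigned()
    out: dict[str, MetricReport] = {}
    for arm, adj in (("signed", signed_adj), ("unsigned", unsigned_adj)):
        arm_cfg = replace(config, seed=config.stage_seed("ablation-run"))
        embeddings, weights, _ = train_pipeline(records, split.train, arm_cfg,
                                                adjacency=adj)
        out[arm] = evaluate_pairs(embeddings, weights, split.test, arm_cfg)
        logger.info("%s arm: f_score %s", arm, out[arm].f_score)
    return out
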