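"""Scoring, metrics, the cross-validation harness, and candidate ranking.

Association scores are inner products of the final (layer-summed) drug and
gene embeddings.  AUC is computed by the tie-aware rank statistic
(Mann-Whitney form), AUPR by step integration of the precision-recall curve,
and the thresholded confusion metrics (recall/precision/F1) binarize at the
top-``n_pos`` rule: exactly as many predicted positives as there are actual
positives, which is deterministic and scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .graph_io import BipartiteGraph, FoldSplit, make_cv_folds
from .trainer import Checkpoint, TrainConfig, compute_final_embeddings, train

__all__ = [
    "MetricsReport",
    "score_pairs",
    "compute_metrics",
    "evaluate_fold",
    "run_cross_validation",
    "rank_candidates",
    "export_embedding_scatter",
]


@dataclass
class MetricsReport:
    """One evaluation's metric bundle (all metrics in [0, 1])."""

    auc: float
    aupr: float
    recall: float
    precision: float
    f1: float
    n_pos: int
    n_neg: int
    threshold_used: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


def score_pairs(final_drug: np.ndarray, final_gene: np.ndarray, pairs) -> np.ndarray:
    """Inner-product association scores for (drug_index, gene_index) pairs."""
    pairs = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=np.int64)
    if pairs.size == 0:
        return np.zeros(0)
    di, gi = pairs[:, 0], pairs[:, 1]
    if di.min() < 0 or di.max() >= final_drug.shape[0] or gi.min() < 0 or gi.max() >= final_gene.shape[0]:
        raise IndexError("pair index out of range")
    return np.einsum("id,id->i", final_drug[di], final_gene[gi])


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted half."""
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _aupr_step(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-integrated precision-recall area (average-precision form).

    Ties are broken by stable index order of the descending sort.
    """
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    precision = tp / k
    n_pos = tp[-1]
    return float(np.sum(precision * y) / n_pos)


def compute_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float | None = None) -> MetricsReport:
    """All five metrics for one scored pair set.

    ``labels`` is binary; both classes must be present.  If ``threshold`` is
    None the confusion metrics use the top-``n_pos`` rule, otherwise scores
    >= threshold are predicted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"metrics need both classes; no {missing} labels present")

    auc = _auc_rank(scores, labels)
    aupr = _aupr_step(scores, labels)

    if threshold is None:
        order = np.argsort(-scores, kind="stable")
        predicted = np.zeros(len(labels), dtype=bool)
        predicted[order[:n_pos]] = True
        threshold_used = float(scores[order[n_pos - 1]])
    else:
        predicted = scores >= threshold
        threshold_used = float(threshold)

    tp = int(np.sum(predicted & (labels == 1)))
    fp = int(np.sum(predicted & (labels == 0)))
    fn = int(np.sum(~predicted & (labels == 1)))
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return MetricsReport(
        auc=auc,
        aupr=aupr,
        recall=recall,
        precision=precision,
        f1=f1,
        n_pos=n_pos,
        n_neg=n_neg,
        threshold_used=threshold_used,
    )


def evaluate_fold(ckpt: Checkpoint, graph: BipartiteGraph, fold: FoldSplit) -> MetricsReport:
    """Score a fold's held-out edges against its sampled negatives."""
    train_graph = graph.subgraph_with_edges(fold.train_edges)
    e_d, e_g = compute_final_embeddings(ckpt, train_graph)
    test_pairs = sorted(fold.test_edges) + sorted(fold.test_negatives)
    labels = np.array([1] * len(fold.test_edges) + [0] * len(fold.test_negatives))
    scores = score_pairs(e_d, e_g, test_pairs)
    return compute_metrics(scores, labels)


def run_cross_validation(
    graph: BipartiteGraph,
    cfg: TrainConfig,
    k: int = 5,
    neg_ratio: float = 1.0,
) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold link-prediction cross-validation.

    Each fold trains from scratch on its training edges only (the SVD view
    included — no leakage of held-out edges), then scores the held-out edges
    against balanced sampled negatives.  The mean report arithmetically
    averages each metric across folds.
    """
    folds = make_cv_folds(graph, k=k, neg_ratio=neg_ratio, seed=cfg.seed)
    reports: list[MetricsReport] = []
    for fold in folds:
        fold_cfg = replace(cfg, seed=(cfg.seed + 1009 * (fold.fold_index + 1)) % (2**31))
        train_graph = graph.subgraph_with_edges(fold.train_edges)
        ckpt, _ = train(train_graph, fold_cfg)
        reports.append(evaluate_fold(ckpt, graph, fold))
    mean = MetricsReport(
        auc=float(np.mean([r.auc for r in reports])),
        aupr=float(np.mean([r.aupr for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        n_pos=int(sum(r.n_pos for r in reports)),
        n_neg=int(sum(r.n_neg for r in reports)),
        threshold_used=float("nan"),
    )
    return reports, mean


def rank_candidates(
    ckpt: Checkpoint,
    graph: BipartiteGraph,
    query: str,
    exclude_known: bool = True,
    top_k: int = 15,
    extra_exclude: set[str] | None = None,
) -> list[tuple[str, float]]:
    """Top-k novel counterpart candidates for a query drug or gene.

    Known associations of the query are excluded (the case-study protocol);
    remaining counterparts are sorted by descending inner-product score with
    stable index tie-breaks.
    """
    e_d, e_g = compute_final_embeddings(ckpt, graph)
    if query in graph.drug_ids:
        qi = graph.drug_ids.index(query)
        scores = e_g @ e_d[qi]
        ids = graph.gene_ids
        known = {j for (i, j) in graph.edges if i == qi}
    elif query in graph.gene_ids:
        qj = graph.gene_ids.index(query)
        scores = e_d @ e_g[qj]
        ids = graph.drug_ids
        known = {i for (i, j) in graph.edges if j == qj}
    else:
        import difflib

        near = difflib.get_close_matches(query, graph.drug_ids + graph.gene_ids, n=5)
        raise KeyError(f"unknown query id {query!r}; nearest known ids: {near}")
    excluded = set(known) if exclude_known else set()
    if extra_exclude:
        excluded |= {k for k, name in enumerate(ids) if name in extra_exclude}
    candidates = [k for k in range(len(ids)) if k not in excluded]
    order = sorted(candidates, key=lambda k: (-scores[k], k))
    return [(ids[k], float(scores[k])) for k in order[:top_k]]


def export_embedding_scatter(ckpt: Checkpoint, graph: BipartiteGraph, path: str) -> None:
    """Optional 2-D scatter of final embeddings (PCA projection) to a file.

    Plotting plumbing only; no cluster-quality claims are made.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e_d, e_g = compute_final_embeddings(ckpt, graph)
    X = np.vstack([e_d, e_g])
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    P = X @ Vt[:2].T
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(P[: graph.m, 0], P[: graph.m, 1], s=8, c="tab:blue", label="drugs", alpha=0.7)
    ax.scatter(P[graph.m :, 0], P[graph.m :, 1], s=8, c="tab:red", label="genes", alpha=0.7)
    ax.legend()
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
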