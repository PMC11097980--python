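"""Training objectives: cross-view InfoNCE, pairwise hinge ranking, L2.

The total objective is

    L = L_r + lambda1 * (L_s^drug + L_s^gene) + lambda2 * ||Theta||_2^2

where L_r is a margin-1 pairwise hinge over (observed, sampled-unobserved)
score pairs, L_s is an InfoNCE term contrasting per-layer embeddings of the
observed view against the augmented view (positives: same node across views;
negatives: other active nodes in the batch), and Theta is the set of base
embedding matrices — the model's only parameters.

All losses come with hand-derived analytic gradients (the *_grad variants);
the trainer composes them with the propagation adjoints for full backprop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import BipartiteGraph

__all__ = [
    "LossConfig",
    "TrainBatch",
    "sample_negatives",
    "info_nce_loss",
    "info_nce_loss_grad",
    "pairwise_hinge_loss",
    "pairwise_hinge_grad",
    "total_loss",
]


@dataclass
class LossConfig:
    """Hyperparameters of the joint objective.

    tau: softmax temperature of the contrastive term (> 0).
    lambda1: weight of the contrastive term (>= 0).
    lambda2: weight of the L2 term on the base embeddings (>= 0).
    neg_per_pos: unobserved pairs sampled per observed pair in the hinge loss.
    cl_keep_prob: probability a node stays active in the contrastive term for
        a given batch (node inactivation regularizer).
    """

    tau: float = 0.2
    lambda1: float = 0.1
    lambda2: float = 1e-5
    neg_per_pos: int = 1
    cl_keep_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be >= 0")
        if self.neg_per_pos < 1:
            raise ValueError("neg_per_pos must be >= 1")
        if not (0 < self.cl_keep_prob <= 1):
            raise ValueError("cl_keep_prob must be in (0, 1]")


@dataclass
class TrainBatch:
    """One mini-batch of ranked pairs plus contrastive activity masks."""

    anchor_drugs: np.ndarray  # (B,)
    pos_genes: np.ndarray  # (B,)
    neg_genes: np.ndarray  # (B, S)
    cl_active_drugs: np.ndarray  # (m,) bool
    cl_active_genes: np.ndarray  # (n,) bool


def sample_negatives(
    graph: BipartiteGraph,
    anchors: np.ndarray,
    S: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each anchor drug, draw S genes it is *not* associated with.

    Uniform over the anchor's complement set, with replacement across the S
    draws (S is typically 1).  Raises if an anchor is associated with every
    gene.
    """
    anchors = np.asarray(anchors)
    n = graph.n
    linked: dict[int, set[int]] = {}
    for i, j in graph.edges:
        linked.setdefault(i, set()).add(j)
    out = np.empty((len(anchors), S), dtype=np.int64)
    for row, a in enumerate(anchors):
        known = linked.get(int(a), set())
        if len(known) >= n:
            raise ValueError(f"drug index {a} is associated with all {n} genes; cannot sample a negative")
        for s in range(S):
            while True:
                j = int(rng.integers(0, n))
                if j not in known:
                    out[row, s] = j
                    break
    return out


def _safe_unit_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize; zero-norm rows map to zero rows (cosine convention 0)."""
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return X / safe[:, None], norms


def _info_nce_layer(Z: np.ndarray, H: np.ndarray, tau: float, want_grad: bool):
    """One layer's batch-wise InfoNCE over B active nodes.

    loss = sum_i [ -C_ii/tau + logsumexp_j C_ij/tau ],  C = cosine matrix.
    Returns (loss, dZ, dH); gradients are None unless requested.
    """
    B = Z.shape[0]
    if B == 0:
        return 0.0, None, None
    Zu, zn = _safe_unit_rows(Z)
    Hu, hn = _safe_unit_rows(H)
    S = (Zu @ Hu.T) / tau
    row_max = S.max(axis=1, keepdims=True)
    expS = np.exp(S - row_max)
    denom = expS.sum(axis=1)
    lse = row_max.ravel() + np.log(denom)
    loss = float(np.sum(lse - np.diag(S)))
    if not want_grad:
        return loss, None, None
    P = expS / denom[:, None]
    dS = (P - np.eye(B)) / tau
    dZu = dS @ Hu
    dHu = dS.T @ Zu
    # back through row normalization; zero-norm rows get zero gradient
    def back(dXu, Xu, norms):
        proj = np.sum(dXu * Xu, axis=1, keepdims=True)
        dX = (dXu - proj * Xu) / np.where(norms > 0, norms, 1.0)[:, None]
        dX[norms == 0] = 0.0
        return dX

    return loss, back(dZu, Zu, zn), back(dHu, Hu, hn)


def info_nce_loss(
    main_layers: list[np.ndarray],
    aug_layers: list[np.ndarray],
    active_mask: np.ndarray,
    tau: float,
) -> float:
    """Cross-view InfoNCE for one node side, summed over layers 0..L.

    Positives pair each active node's observed-view embedding with its
    augmented-view embedding at the same layer; the softmax denominator runs
    over the augmented embeddings of all active nodes in the batch.  Inactive
    nodes contribute nothing and never appear as negatives.
    """
    loss, _, _ = info_nce_loss_grad(main_layers, aug_layers, active_mask, tau, want_grad=False)
    return loss


def info_nce_loss_grad(
    main_layers: list[np.ndarray],
    aug_layers: list[np.ndarray],
    active_mask: np.ndarray,
    tau: float,
    want_grad: bool = True,
):
    """InfoNCE plus per-layer gradients w.r.t. the full embedding matrices."""
    if len(main_layers) != len(aug_layers):
        raise ValueError("main and augmented layer lists must have equal length")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    active_mask = np.asarray(active_mask, dtype=bool)
    idx = np.nonzero(active_mask)[0]
    total = 0.0
    grads_main = [np.zeros_like(Z) for Z in main_layers] if want_grad else None
    grads_aug = [np.zeros_like(H) for H in aug_layers] if want_grad else None
    for l, (Z, H) in enumerate(zip(main_layers, aug_layers)):
        if Z.shape != H.shape:
            raise ValueError(f"layer {l}: view shapes differ ({Z.shape} vs {H.shape})")
        loss, dZ, dH = _info_nce_layer(Z[idx], H[idx], tau, want_grad)
        total += loss
        if want_grad and dZ is not None:
            grads_main[l][idx] += dZ
            grads_aug[l][idx] += dH
    return total, grads_main, grads_aug


def pairwise_hinge_loss(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Margin-1 ranking loss: sum_i sum_s max(0, 1 - pos_i + neg_is)."""
    loss, _, _ = pairwise_hinge_grad(np.asarray(pos_scores, float), np.asarray(neg_scores, float))
    return loss


def pairwise_hinge_grad(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """Hinge loss with subgradients w.r.t. the two score arrays."""
    pos = np.asarray(pos_scores, dtype=float).reshape(-1)
    neg = np.asarray(neg_scores, dtype=float)
    if neg.ndim == 1:
        neg = neg[:, None]
    if neg.shape[0] != pos.shape[0]:
        raise ValueError("pos_scores and neg_scores disagree on the anchor count")
    margins = 1.0 - pos[:, None] + neg
    violated = margins > 0
    loss = float(margins[violated].sum())
    d_neg = violated.astype(float)
    d_pos = -d_neg.sum(axis=1)
    return loss, d_pos, d_neg


def total_loss(L_r: float, L_s_drug: float, L_s_gene: float, param_sq_norm: float, cfg: LossConfig) -> float:
    """Weighted joint objective; Theta is the pair of base embedding matrices."""
    return float(L_r + cfg.lambda1 * (L_s_drug + L_s_gene) + cfg.lambda2 * param_sq_norm)
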