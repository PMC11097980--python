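"""Global-collaborative augmented view via truncated randomized SVD.

The normalized adjacency is factored as A_norm ~ U_t S_t V_t^T with the top-t
singular triplets (randomized range finder + power iterations).  Propagating
embeddings over the low-rank reconstruction injects global collaborative
signal; the reconstruction itself is never materialized — all products are
computed in factored form, so one layer costs O((m + n) t d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .gcn_encoder import EmbeddingState, PropagationOp, aggregate_layers, get_activation

__all__ = [
    "SVDView",
    "FactoredOp",
    "truncated_randomized_svd",
    "reconstruct",
    "svd_propagate_layer",
    "encode_augmented",
]


@dataclass
class SVDView:
    """Truncated SVD factors of the normalized adjacency.

    ``U_t`` (m x t) and ``V_t`` (n x t) have orthonormal columns; ``s`` holds
    the top-t singular values in non-increasing order.
    """

    U_t: np.ndarray
    s: np.ndarray
    V_t: np.ndarray

    @property
    def t(self) -> int:
        return len(self.s)

    @property
    def S_t(self) -> np.ndarray:
        return np.diag(self.s)


def truncated_randomized_svd(
    A_norm: sp.spmatrix | np.ndarray,
    t: int,
    oversample: int = 10,
    power_iters: int = 4,
    seed: int = 0,
) -> SVDView:
    """Top-t randomized SVD of the (sparse) normalized adjacency.

    Uses a Gaussian range finder with ``t + oversample`` probes and
    ``power_iters`` subspace iterations, then an exact SVD of the projected
    small matrix.  Deterministic under ``seed``.  Sign convention: each
    (U, V) column pair is flipped so the largest-magnitude entry of the U
    column is positive, which makes the factors test-stable (the
    reconstruction is invariant to these flips).
    """
    m, n = A_norm.shape
    if not (1 <= t <= min(m, n)):
        raise ValueError(f"rank t={t} out of range [1, {min(m, n)}]")
    U, s, Vt = randomized_svd(
        sp.csr_matrix(A_norm),
        n_components=t,
        n_oversamples=oversample,
        n_iter=power_iters,
        random_state=seed,
    )
    V = Vt.T
    # deterministic sign: largest-|.| entry of each U column made positive
    anchor = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[anchor, np.arange(t)])
    signs[signs == 0] = 1.0
    return SVDView(U_t=U * signs, s=s, V_t=V * signs)


def reconstruct(view: SVDView) -> np.ndarray:
    """Materialize U_t S_t V_t^T (testing/diagnostics only; O(m n t))."""
    return (view.U_t * view.s) @ view.V_t.T


class FactoredOp(PropagationOp):
    """Propagation over the rank-t reconstruction, kept in factored form."""

    def __init__(self, view: SVDView):
        self.view = view

    def mv_drug(self, X_gene):
        return self.view.U_t @ (self.view.s[:, None] * (self.view.V_t.T @ X_gene))

    def mv_gene(self, X_drug):
        return self.view.V_t @ (self.view.s[:, None] * (self.view.U_t.T @ X_drug))

    # The reconstruction is symmetric in its factors, so the adjoints mirror
    # the forward maps with U and V exchanged.
    def rmv_drug(self, G_drug):
        return self.mv_gene(G_drug)

    def rmv_gene(self, G_gene):
        return self.mv_drug(G_gene)


def svd_propagate_layer(
    view: SVDView,
    prev_drug: np.ndarray,
    prev_gene: np.ndarray,
    activation: str = "leaky_relu",
) -> tuple[np.ndarray, np.ndarray]:
    """One aggregation round over the SVD-reconstructed graph (no dropout)."""
    if prev_drug.shape[1] != prev_gene.shape[1]:
        raise ValueError("drug/gene embeddings must share the embedding width")
    if view.U_t.shape[0] != prev_drug.shape[0] or view.V_t.shape[0] != prev_gene.shape[0]:
        raise ValueError("SVD view shape inconsistent with embeddings")
    sigma, _ = get_activation(activation)
    op = FactoredOp(view)
    h_drug = sigma(op.mv_drug(prev_gene))
    h_gene = sigma(op.mv_gene(prev_drug))
    return h_drug, h_gene


def encode_augmented(
    view: SVDView,
    state: EmbeddingState,
    L: int = 2,
    activation: str = "leaky_relu",
) -> EmbeddingState:
    """Fill the augmented-view layer stack, mirroring the main view's chaining.

    Layer 0 is the same base embeddings as the main view; each layer consumes
    the previous augmented layer's outputs.
    """
    if L < 1:
        raise ValueError("layer count L must be >= 1")
    hd, hg = state.E_drug, state.E_gene
    state.aug_layers_drug = [hd]
    state.aug_layers_gene = [hg]
    for _ in range(L):
        hd, hg = svd_propagate_layer(view, hd, hg, activation=activation)
        state.aug_layers_drug.append(hd)
        state.aug_layers_gene.append(hg)
    return state
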