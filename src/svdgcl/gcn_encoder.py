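"""ID-embedding GCN encoder over the bipartite drug-gene graph.

The model is embedding-only: the learnable parameters are the layer-0 drug and
gene embedding matrices.  One propagation layer computes

    z_drug = sigma(p(A_norm) @ prev_gene)
    z_gene = sigma(p(A_norm)^T @ prev_drug)

where ``p`` drops each nonzero adjacency entry independently (edge dropout,
inverted scaling) during training and is the identity at evaluation time.
Final embeddings are the elementwise sum over layers 0..L, so with an identity
activation the encoder is a linear map of the base embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .graph_io import BipartiteGraph

__all__ = [
    "EmbeddingState",
    "PropagationOp",
    "SparseOp",
    "MaskedOp",
    "init_embeddings",
    "drop_edges",
    "propagate_layer",
    "aggregate_layers",
    "encode",
    "leaky_relu",
    "identity",
    "get_activation",
]

LEAKY_SLOPE = 0.5


def leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def leaky_relu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, LEAKY_SLOPE)


def identity(x: np.ndarray) -> np.ndarray:
    return x


def identity_grad(x: np.ndarray) -> np.ndarray:
    return np.ones_like(x)


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "leaky_relu": (leaky_relu, leaky_relu_grad),
    "identity": (identity, identity_grad),
}


def get_activation(name: str) -> tuple[Callable, Callable]:
    """Return (activation, derivative) by name ('leaky_relu' or 'identity')."""
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}") from None


class PropagationOp:
    """Linear message-passing operator over a bipartite graph view.

    Encapsulates multiplication by an (implicit) m x n view matrix B:
    ``mv_drug``  : X_gene (n x d) -> B  @ X_gene  (m x d)   drug update
    ``mv_gene``  : X_drug (m x d) -> B^T @ X_drug (n x d)   gene update
    ``rmv_drug`` : adjoint of mv_drug (gradient back to the gene side)
    ``rmv_gene`` : adjoint of mv_gene (gradient back to the drug side)
    """

    def mv_drug(self, X_gene: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def mv_gene(self, X_drug: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def rmv_drug(self, G_drug: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def rmv_gene(self, G_gene: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SparseOp(PropagationOp):
    """Propagation through an explicit sparse matrix (the observed view)."""

    def __init__(self, P: sp.spmatrix):
        self.P = sp.csr_matrix(P)
        self.PT = sp.csr_matrix(self.P.T)

    def mv_drug(self, X_gene):
        return self.P @ X_gene

    def mv_gene(self, X_drug):
        return self.PT @ X_drug

    def rmv_drug(self, G_drug):
        return self.PT @ G_drug

    def rmv_gene(self, G_gene):
        return self.P @ G_gene


class MaskedOp(PropagationOp):
    """Propagation with node rows zeroed before aggregation (node dropping)."""

    def __init__(self, base: PropagationOp, drug_keep: np.ndarray, gene_keep: np.ndarray):
        self.base = base
        self.drug_keep = drug_keep.astype(float).reshape(-1, 1)
        self.gene_keep = gene_keep.astype(float).reshape(-1, 1)

    def mv_drug(self, X_gene):
        return self.base.mv_drug(self.gene_keep * X_gene)

    def mv_gene(self, X_drug):
        return self.base.mv_gene(self.drug_keep * X_drug)

    def rmv_drug(self, G_drug):
        return self.gene_keep * self.base.rmv_drug(G_drug)

    def rmv_gene(self, G_gene):
        return self.drug_keep * self.base.rmv_gene(G_gene)


@dataclass
class EmbeddingState:
    """Per-layer embeddings for the main and augmented views.

    ``main_layers_*[0]`` and ``aug_layers_*[0]`` both hold the (shared) base
    embeddings; ``final_*`` is the elementwise layer sum of the main view.
    """

    E_drug: np.ndarray
    E_gene: np.ndarray
    main_layers_drug: list[np.ndarray] = field(default_factory=list)
    main_layers_gene: list[np.ndarray] = field(default_factory=list)
    aug_layers_drug: list[np.ndarray] = field(default_factory=list)
    aug_layers_gene: list[np.ndarray] = field(default_factory=list)
    final_drug: np.ndarray | None = None
    final_gene: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.E_drug.shape[1]


def init_embeddings(m: int, n: int, d: int, seed: int = 0) -> EmbeddingState:
    """Xavier-uniform base embeddings, deterministic under ``seed``.

    Entries are i.i.d. U(-a, a) with a = sqrt(6 / (rows + d)), the standard
    Glorot fan-based scale.
    """
    if d < 1:
        raise ValueError("embedding width d must be >= 1")
    rng = np.random.default_rng(seed)
    a_d = np.sqrt(6.0 / (m + d))
    a_g = np.sqrt(6.0 / (n + d))
    E_drug = rng.uniform(-a_d, a_d, size=(m, d))
    E_gene = rng.uniform(-a_g, a_g, size=(n, d))
    state = EmbeddingState(E_drug=E_drug, E_gene=E_gene)
    state.main_layers_drug = [E_drug]
    state.main_layers_gene = [E_gene]
    state.aug_layers_drug = [E_drug]
    state.aug_layers_gene = [E_gene]
    return state


def drop_edges(A_norm: sp.spmatrix, rate: float, rng: np.random.Generator) -> sp.csr_matrix:
    """Edge dropout with inverted scaling.

    Each nonzero is zeroed independently with probability ``rate``; survivors
    are rescaled by 1/(1-rate) so the operator is unbiased in expectation.
    """
    if not (0 <= rate < 1):
        raise ValueError("edge_dropout must be in [0, 1)")
    A = sp.csr_matrix(A_norm, copy=True)
    if rate == 0 or A.nnz == 0:
        return A
    keep = rng.random(A.nnz) >= rate
    A.data = np.where(keep, A.data / (1.0 - rate), 0.0)
    A.eliminate_zeros()
    return A


def propagate_layer(
    A_norm: sp.spmatrix,
    prev_drug: np.ndarray,
    prev_gene: np.ndarray,
    edge_dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    activation: str = "leaky_relu",
    mode: str = "train",
) -> tuple[np.ndarray, np.ndarray]:
    """One round of bipartite neighbor aggregation.

    In train mode the adjacency goes through edge dropout (fresh mask); in
    eval mode the operator is deterministic.
    """
    if prev_drug.shape[1] != prev_gene.shape[1]:
        raise ValueError("drug/gene embeddings must share the embedding width")
    if A_norm.shape != (prev_drug.shape[0], prev_gene.shape[0]):
        raise ValueError(
            f"adjacency shape {A_norm.shape} inconsistent with embeddings "
            f"({prev_drug.shape[0]} drugs, {prev_gene.shape[0]} genes)"
        )
    sigma, _ = get_activation(activation)
    if mode == "train" and edge_dropout > 0:
        if rng is None:
            raise ValueError("rng required for edge dropout in train mode")
        P = drop_edges(A_norm, edge_dropout, rng)
    else:
        P = sp.csr_matrix(A_norm)
    op = SparseOp(P)
    z_drug = sigma(op.mv_drug(prev_gene))
    z_gene = sigma(op.mv_gene(prev_drug))
    return z_drug, z_gene


def aggregate_layers(layers: list[np.ndarray]) -> np.ndarray:
    """Elementwise sum over layers 0..L (the final-embedding rule)."""
    if not layers:
        raise ValueError("cannot aggregate an empty layer list")
    out = np.zeros_like(layers[0])
    for layer in layers:
        if layer.shape != out.shape:
            raise ValueError("all layers must share a shape")
        out += layer
    return out


def encode(
    graph: BipartiteGraph,
    state: EmbeddingState,
    L: int = 2,
    edge_dropout: float = 0.25,
    rng: np.random.Generator | None = None,
    activation: str = "leaky_relu",
    mode: str = "eval",
) -> EmbeddingState:
    """Run L propagation layers on the observed view and aggregate.

    Layer 0 is the base embeddings; each subsequent layer consumes the
    previous layer's outputs.  Fills ``main_layers_*`` and ``final_*`` in
    place and returns the state.
    """
    if L < 1:
        raise ValueError("layer count L must be >= 1")
    zd, zg = state.E_drug, state.E_gene
    state.main_layers_drug = [zd]
    state.main_layers_gene = [zg]
    for _ in range(L):
        zd, zg = propagate_layer(
            graph.A_norm, zd, zg, edge_dropout=edge_dropout, rng=rng, activation=activation, mode=mode
        )
        state.main_layers_drug.append(zd)
        state.main_layers_gene.append(zg)
    state.final_drug = aggregate_layers(state.main_layers_drug)
    state.final_gene = aggregate_layers(state.main_layers_gene)
    return state
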