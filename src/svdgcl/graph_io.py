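"""Bipartite drug-gene association graphs: I/O, normalization, CV splits, synthetic data.

The central object is :class:`BipartiteGraph`, a binary drug x gene incidence
structure built from a two-column edge list.  Degree normalization follows the
symmetric scheme used throughout the LightGCN lineage of bipartite GCNs,

    A_norm[i, j] = A[i, j] / sqrt(deg_drug(i) * deg_gene(j)),

with zero-degree rows/columns mapped to zero (such nodes simply receive no
messages during propagation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BipartiteGraph",
    "FoldSplit",
    "SyntheticSpec",
    "load_edge_list",
    "build_graph",
    "normalize_adjacency",
    "make_cv_folds",
    "generate_synthetic_graph",
    "graph_summary",
    "write_fold_files",
]


@dataclass
class BipartiteGraph:
    """A binary bipartite association graph between drugs and genes.

    Attributes
    ----------
    drug_ids, gene_ids:
        Identifier strings in index order (first-appearance order for loaded
        edge lists).
    edges:
        Set of ``(drug_index, gene_index)`` pairs; no duplicates by
        construction.
    A:
        ``m x n`` binary CSR association matrix.
    A_norm:
        Symmetric degree-normalized adjacency, same sparsity pattern as ``A``.
    """

    drug_ids: list[str]
    gene_ids: list[str]
    edges: set[tuple[int, int]]
    A: sp.csr_matrix = field(repr=False)
    A_norm: sp.csr_matrix = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def subgraph_with_edges(self, edges: set[tuple[int, int]]) -> "BipartiteGraph":
        """Same vocabulary, restricted edge set (used for training folds)."""
        A = edges_to_matrix(edges, self.m, self.n)
        return BipartiteGraph(
            drug_ids=self.drug_ids,
            gene_ids=self.gene_ids,
            edges=set(edges),
            A=A,
            A_norm=normalize_adjacency(A),
        )


@dataclass
class FoldSplit:
    """One cross-validation fold for link prediction.

    ``train_edges`` and ``test_edges`` partition the known associations;
    ``test_negatives`` are sampled non-edges used as the negative class when
    scoring the held-out fold.
    """

    fold_index: int
    train_edges: set[tuple[int, int]]
    test_edges: set[tuple[int, int]]
    test_negatives: set[tuple[int, int]]


@dataclass
class SyntheticSpec:
    """Planted-block bipartite graph specification.

    Drugs and genes are assigned to ``n_blocks`` communities round-robin; a
    drug-gene pair is associated with probability ``p_in`` when the two nodes
    share a block and ``p_out`` otherwise.  This mimics the modular structure
    of curated drug-gene interaction databases (families of drugs hitting
    families of targets) at desk scale.
    """

    m: int = 100
    n: int = 60
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_blocks > min(self.m, self.n):
            raise ValueError("n_blocks must be <= min(m, n)")


def edges_to_matrix(edges: Sequence[tuple[int, int]] | set[tuple[int, int]], m: int, n: int) -> sp.csr_matrix:
    """Binary CSR incidence matrix from an edge collection."""
    if len(edges) == 0:
        return sp.csr_matrix((m, n))
    rows, cols = zip(*sorted(edges))
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(m, n))


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric degree normalization D_d^{-1/2} A D_g^{-1/2}.

    Zero-degree rows/columns stay all-zero (no NaN/Inf).  The sparsity
    pattern of the result equals that of ``A``.
    """
    A = sp.csr_matrix(A, dtype=float)
    deg_d = np.asarray(A.sum(axis=1)).ravel()
    deg_g = np.asarray(A.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt_d = np.where(deg_d > 0, 1.0 / np.sqrt(np.maximum(deg_d, 1e-300)), 0.0)
        inv_sqrt_g = np.where(deg_g > 0, 1.0 / np.sqrt(np.maximum(deg_g, 1e-300)), 0.0)
    Dd = sp.diags(inv_sqrt_d)
    Dg = sp.diags(inv_sqrt_g)
    return sp.csr_matrix(Dd @ A @ Dg)


def build_graph(drug_ids: list[str], gene_ids: list[str], edges: set[tuple[int, int]]) -> BipartiteGraph:
    A = edges_to_matrix(edges, len(drug_ids), len(gene_ids))
    return BipartiteGraph(drug_ids, gene_ids, set(edges), A, normalize_adjacency(A))


def load_edge_list(path: str | Path, header: bool = False) -> BipartiteGraph:
    """Read a tab-separated drug/gene edge list into a graph.

    Parameters
    ----------
    path:
        TSV file with at least two columns: drug identifier, gene identifier.
        Extra columns are ignored.  Duplicate rows collapse to one edge
        (associations are binary).
    header:
        If True, the first line is skipped.

    Indices are assigned in first-appearance order so that outputs are stable
    across runs.
    """
    path = Path(path)
    drug_index: dict[str, int] = {}
    gene_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed row at line {lineno}: need >= 2 tab-separated fields")
            d, g = fields[0].strip(), fields[1].strip()
            di = drug_index.setdefault(d, len(drug_index))
            gi = gene_index.setdefault(g, len(gene_index))
            edges.add((di, gi))
    if not edges:
        raise ValueError(f"{path}: no associations")
    return build_graph(list(drug_index), list(gene_index), edges)


def save_edge_list(graph: BipartiteGraph, path: str | Path, header: bool = False) -> None:
    """Write the graph's edges as a two-column TSV (inverse of load_edge_list)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("drug_id\tgene_id\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{graph.drug_ids[i]}\t{graph.gene_ids[j]}\n")


def sample_non_edges(
    graph: BipartiteGraph,
    count: int,
    rng: np.random.Generator,
    forbidden: set[tuple[int, int]] | None = None,
) -> set[tuple[int, int]]:
    """Uniform sample (without replacement) of pairs absent from the graph.

    ``forbidden`` extends the exclusion set beyond the graph's own edges
    (e.g. negatives already claimed by another fold).
    """
    excluded = set(graph.edges)
    if forbidden:
        excluded |= forbidden
    pool_size = graph.m * graph.n - len(excluded)
    if count > pool_size:
        raise ValueError(f"requested {count} negatives but only {pool_size} non-edges are available")
    chosen: set[tuple[int, int]] = set()
    # Rejection sampling; cheap as long as the graph is reasonably sparse.
    # Falls back to exhaustive enumeration if the acceptance rate is poor.
    dense = (len(excluded) + count) > 0.5 * graph.m * graph.n
    if dense:
        all_pairs = [(i, j) for i in range(graph.m) for j in range(graph.n) if (i, j) not in excluded]
        idx = rng.choice(len(all_pairs), size=count, replace=False)
        return {all_pairs[k] for k in idx}
    while len(chosen) < count:
        need = count - len(chosen)
        ii = rng.integers(0, graph.m, size=2 * need + 8)
        jj = rng.integers(0, graph.n, size=2 * need + 8)
        for i, j in zip(ii, jj):
            pair = (int(i), int(j))
            if pair not in excluded and pair not in chosen:
                chosen.add(pair)
                if len(chosen) == count:
                    break
    return chosen


def make_cv_folds(
    graph: BipartiteGraph,
    k: int = 5,
    neg_ratio: float = 1.0,
    seed: int = 0,
) -> list[FoldSplit]:
    """Partition the known edges into ``k`` folds for cross-validation.

    Edges are randomly split into ``k`` parts whose sizes differ by at most
    one.  For each fold, the held-out edges are paired with
    ``neg_ratio * |test_edges|`` non-edges sampled uniformly without
    replacement (balanced evaluation by default).  Fully determined by
    ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > graph.n_edges:
        raise ValueError(f"k={k} exceeds the number of edges ({graph.n_edges})")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    perm = rng.permutation(len(edges))
    parts = np.array_split(perm, k)
    folds: list[FoldSplit] = []
    for fold_index, part in enumerate(parts):
        test = {edges[i] for i in part}
        train = set(graph.edges) - test
        n_neg = int(round(neg_ratio * len(test)))
        negatives = sample_non_edges(graph, n_neg, rng)
        folds.append(FoldSplit(fold_index, train, test, negatives))
    return folds


def generate_synthetic_graph(spec: SyntheticSpec) -> tuple[BipartiteGraph, np.ndarray, np.ndarray]:
    """Sample a planted-block bipartite graph.

    Returns the graph plus the planted block labels for drugs and genes
    (round-robin assignment: node ``i`` belongs to block ``i % n_blocks``).

    Raises if the draw produced zero edges (raise ``p_in`` or the sizes).
    """
    rng = np.random.default_rng(spec.seed)
    drug_blocks = np.arange(spec.m) % spec.n_blocks
    gene_blocks = np.arange(spec.n) % spec.n_blocks
    same_block = drug_blocks[:, None] == gene_blocks[None, :]
    prob = np.where(same_block, spec.p_in, spec.p_out)
    mask = rng.random((spec.m, spec.n)) < prob
    edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(mask))}
    if not edges:
        raise ValueError("synthetic draw produced zero edges; increase p_in or the graph size")
    drug_ids = [f"D{i:04d}" for i in range(spec.m)]
    gene_ids = [f"G{j:04d}" for j in range(spec.n)]
    return build_graph(drug_ids, gene_ids, edges), drug_blocks, gene_blocks


def graph_summary(graph: BipartiteGraph) -> dict:
    return {
        "n_drugs": graph.m,
        "n_genes": graph.n,
        "n_edges": graph.n_edges,
        "density": graph.n_edges / (graph.m * graph.n),
    }


def write_fold_files(graph: BipartiteGraph, folds: list[FoldSplit], path: str | Path) -> None:
    """Write fold assignments as a TSV: fold, role(train|test|neg), drug_id, gene_id."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fold\trole\tdrug_id\tgene_id\n")
        for fold in folds:
            for role, pairs in (("train", fold.train_edges), ("test", fold.test_edges), ("neg", fold.test_negatives)):
                for i, j in sorted(pairs):
                    fh.write(f"{fold.fold_index}\t{role}\t{graph.drug_ids[i]}\t{graph.gene_ids[j]}\n")


def write_summary_json(graph: BipartiteGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_summary(graph), fh, indent=2)
        fh.write("\n")
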