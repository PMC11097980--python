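"""End-to-end training loop, ablation variants, and checkpointing.

Only the base embedding matrices are learnable (the propagation stack has no
weight matrices), so optimization is plain reverse-mode differentiation of
the joint objective through the layer chain, implemented directly in NumPy,
followed by Adam updates.

Variants (the ablation switchboard):

=========  =================================================================
full       SVD-reconstructed global view as the contrastive partner
gcn_none   no contrastive term at all (plain GCN + ranking loss)
gcn_ed     edge perturbation: contrast against a fresh edge-dropped view
gcn_nd     node dropping: contrast against a view with node rows zeroed
gcn_rw     random walk: per-layer fresh edge-sampled subgraphs
mf         matrix factorization: no propagation, scores from base embeddings
=========  =================================================================
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .gcn_encoder import (
    EmbeddingState,
    PropagationOp,
    MaskedOp,
    SparseOp,
    drop_edges,
    encode,
    get_activation,
    init_embeddings,
)
from .graph_io import BipartiteGraph
from .objectives import (
    LossConfig,
    TrainBatch,
    info_nce_loss_grad,
    pairwise_hinge_grad,
    sample_negatives,
)
from .svd_augmentation import FactoredOp, SVDView, encode_augmented, truncated_randomized_svd

__all__ = [
    "VARIANTS",
    "TrainConfig",
    "Checkpoint",
    "train",
    "make_variant_view",
    "batch_loss_and_grad",
    "compute_final_embeddings",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("full", "gcn_none", "gcn_ed", "gcn_nd", "gcn_rw", "mf")

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    """All training hyperparameters.

    Defaults: embedding width 256 and 2 propagation layers (the sensitivity
    optima), 300 epochs; SVD rank 5, temperature 0.2, contrastive weight 0.1
    and L2 weight 1e-5 are package defaults surfaced here.
    """

    d: int = 256
    L: int = 2
    t: int = 5
    tau: float = 0.2
    lambda1: float = 0.1
    lambda2: float = 1e-5
    edge_dropout: float = 0.25
    cl_keep_prob: float = 0.5
    neg_per_pos: int = 1
    node_drop_rate: float = 0.1
    epochs: int = 300
    batch_size: int = 1024
    learning_rate: float = 1e-3
    seed: int = 0
    variant: str = "full"
    activation: str = "leaky_relu"
    svd_oversample: int = 10
    svd_power_iters: int = 4
    gene_anchors: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        for name in ("d", "L", "t", "epochs", "batch_size", "neg_per_pos"):
            if getattr(self, name) < (0 if name == "epochs" else 1):
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.edge_dropout < 1):
            raise ValueError("edge_dropout must be in [0, 1)")
        if not (0 <= self.node_drop_rate < 1):
            raise ValueError("node_drop_rate must be in [0, 1)")
        get_activation(self.activation)

    def loss_config(self) -> LossConfig:
        return LossConfig(
            tau=self.tau,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            neg_per_pos=self.neg_per_pos,
            cl_keep_prob=self.cl_keep_prob,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "TrainConfig":
        """Load a flat key/value YAML config; keyword overrides win."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class Checkpoint:
    """Trained state: config snapshot, embeddings, SVD factors, loss tail."""

    config: TrainConfig
    E_drug: np.ndarray
    E_gene: np.ndarray
    svd_view: SVDView | None
    epoch: int
    loss_components: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# forward/backward through a propagation chain
# ---------------------------------------------------------------------------


def _chain_forward(Ed, Eg, ops, sigma):
    """Layer stacks plus pre-activations for a list of per-layer operators."""
    Zd, Zg, Md, Mg = [Ed], [Eg], [], []
    for op in ops:
        md = op.mv_drug(Zg[-1])
        mg = op.mv_gene(Zd[-1])
        Md.append(md)
        Mg.append(mg)
        Zd.append(sigma(md))
        Zg.append(sigma(mg))
    return Zd, Zg, Md, Mg


def _chain_backward(dZd, dZg, Md, Mg, ops, dsigma):
    """Accumulate layer gradients down the chain; returns grads at layer 0."""
    for l in range(len(ops), 0, -1):
        dmd = dZd[l] * dsigma(Md[l - 1])
        dmg = dZg[l] * dsigma(Mg[l - 1])
        dZg[l - 1] += ops[l - 1].rmv_drug(dmd)
        dZd[l - 1] += ops[l - 1].rmv_gene(dmg)
    return dZd[0], dZg[0]


def batch_loss_and_grad(
    E_drug: np.ndarray,
    E_gene: np.ndarray,
    main_ops: list[PropagationOp],
    aug_ops: list[PropagationOp] | None,
    batch: TrainBatch,
    cfg: LossConfig,
    activation: str = "leaky_relu",
):
    """Joint objective and its analytic gradient w.r.t. the base embeddings.

    Deterministic given the operators and batch (all stochasticity — dropout
    masks, negatives, activity masks — is materialized in the inputs), which
    is what makes direct finite-difference verification possible.

    Returns ``(total, components, dE_drug, dE_gene)`` with components keyed
    ``L_r``, ``L_s_d``, ``L_s_g``, ``L2`` (the weighted L2 term).
    """
    sigma, dsigma = get_activation(activation)
    Zd, Zg, Md, Mg = _chain_forward(E_drug, E_gene, main_ops, sigma)
    ed = sum(Zd[1:], Zd[0].copy())
    eg = sum(Zg[1:], Zg[0].copy())

    a, p, N = batch.anchor_drugs, batch.pos_genes, batch.neg_genes
    pos_scores = np.einsum("id,id->i", ed[a], eg[p])
    neg_scores = np.einsum("id,isd->is", ed[a], eg[N])
    L_r, d_pos, d_neg = pairwise_hinge_grad(pos_scores, neg_scores)

    ded = np.zeros_like(ed)
    deg = np.zeros_like(eg)
    np.add.at(ded, a, d_pos[:, None] * eg[p] + np.einsum("is,isd->id", d_neg, eg[N]))
    np.add.at(deg, p, d_pos[:, None] * ed[a])
    d = ed.shape[1]
    np.add.at(deg, N.ravel(), (d_neg[:, :, None] * ed[a][:, None, :]).reshape(-1, d))

    L_s_d = L_s_g = 0.0
    g_main_d = g_aug_d = g_main_g = g_aug_g = None
    use_cl = aug_ops is not None and cfg.lambda1 > 0
    if aug_ops is not None:
        Hd, Hg, MdA, MgA = _chain_forward(E_drug, E_gene, aug_ops, sigma)
        L_s_d, g_main_d, g_aug_d = info_nce_loss_grad(Zd, Hd, batch.cl_active_drugs, cfg.tau)
        L_s_g, g_main_g, g_aug_g = info_nce_loss_grad(Zg, Hg, batch.cl_active_genes, cfg.tau)

    sq_norm = float(np.sum(E_drug**2) + np.sum(E_gene**2))
    total = L_r + cfg.lambda1 * (L_s_d + L_s_g) + cfg.lambda2 * sq_norm

    # gradients hitting each main layer: the layer-sum rule spreads the score
    # gradient to every layer; the contrastive term adds per-layer pieces
    dZd_list = [ded.copy() for _ in Zd]
    dZg_list = [deg.copy() for _ in Zg]
    if use_cl:
        for l in range(len(Zd)):
            dZd_list[l] += cfg.lambda1 * g_main_d[l]
            dZg_list[l] += cfg.lambda1 * g_main_g[l]
    dEd, dEg = _chain_backward(dZd_list, dZg_list, Md, Mg, main_ops, dsigma)

    if use_cl:
        dHd_list = [cfg.lambda1 * g_aug_d[l] for l in range(len(Zd))]
        dHg_list = [cfg.lambda1 * g_aug_g[l] for l in range(len(Zg))]
        dEd_aug, dEg_aug = _chain_backward(dHd_list, dHg_list, MdA, MgA, aug_ops, dsigma)
        dEd = dEd + dEd_aug
        dEg = dEg + dEg_aug

    dEd = dEd + 2.0 * cfg.lambda2 * E_drug
    dEg = dEg + 2.0 * cfg.lambda2 * E_gene
    components = {"L_r": L_r, "L_s_d": L_s_d, "L_s_g": L_s_g, "L2": cfg.lambda2 * sq_norm}
    return total, components, dEd, dEg


# ---------------------------------------------------------------------------
# variant switchboard
# ---------------------------------------------------------------------------


def build_aug_ops(
    variant: str,
    graph: BipartiteGraph,
    cfg: TrainConfig,
    rng: np.random.Generator,
    svd_view: SVDView | None = None,
) -> list[PropagationOp] | None:
    """Per-layer operators for the augmented (contrastive partner) view."""
    if variant in ("gcn_none", "mf"):
        return None
    if variant == "full":
        if svd_view is None:
            raise ValueError("the full variant needs a precomputed SVD view")
        op = FactoredOp(svd_view)
        return [op] * cfg.L
    if variant == "gcn_ed":
        op = SparseOp(drop_edges(graph.A_norm, cfg.edge_dropout, rng))
        return [op] * cfg.L
    if variant == "gcn_nd":
        drug_keep = rng.random(graph.m) >= cfg.node_drop_rate
        gene_keep = rng.random(graph.n) >= cfg.node_drop_rate
        op = MaskedOp(SparseOp(graph.A_norm), drug_keep, gene_keep)
        return [op] * cfg.L
    if variant == "gcn_rw":
        return [SparseOp(drop_edges(graph.A_norm, cfg.edge_dropout, rng)) for _ in range(cfg.L)]
    raise ValueError(f"unknown variant {variant!r}")


def make_variant_view(
    variant: str,
    graph: BipartiteGraph,
    state: EmbeddingState,
    cfg: TrainConfig,
    rng: np.random.Generator,
    svd_view: SVDView | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Fill the augmented layer stacks for a perturbation/SVD variant."""
    if variant in ("gcn_none", "mf"):
        raise ValueError(f"variant {variant!r} has no augmented view")
    ops = build_aug_ops(variant, graph, cfg, rng, svd_view)
    sigma, _ = get_activation(cfg.activation)
    Hd, Hg, _, _ = _chain_forward(state.E_drug, state.E_gene, ops, sigma)
    state.aug_layers_drug = Hd
    state.aug_layers_gene = Hg
    return Hd, Hg


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------


class _Adam:
    """Minimal Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + eps))
        return out


def _draw_active_mask(size: int, members: np.ndarray, keep_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Node-inactivation mask: batch members each kept with keep_prob."""
    mask = np.zeros(size, dtype=bool)
    members = np.unique(members)
    keep = rng.random(len(members)) < keep_prob
    mask[members[keep]] = True
    return mask


def train(graph: BipartiteGraph, cfg: TrainConfig) -> tuple[Checkpoint, list[dict]]:
    """Optimize the base embeddings on one training graph.

    Returns the final checkpoint and a per-epoch log of loss components
    (keys: epoch, L_r, L_s_d, L_s_g, L2, total).  Fully deterministic under
    ``cfg.seed``.  With ``epochs=0`` the checkpoint equals the
    initialization.
    """
    if graph.n_edges == 0:
        raise ValueError("training requires a non-empty graph")
    rng = np.random.default_rng(cfg.seed)
    state = init_embeddings(graph.m, graph.n, cfg.d, seed=cfg.seed)
    Ed, Eg = state.E_drug.copy(), state.E_gene.copy()
    loss_cfg = cfg.loss_config()

    svd_view = None
    if cfg.variant == "full":
        t = min(cfg.t, graph.m, graph.n)
        svd_view = truncated_randomized_svd(
            graph.A_norm, t, oversample=cfg.svd_oversample, power_iters=cfg.svd_power_iters, seed=cfg.seed
        )

    # adjacency sets for fast negative sampling
    linked: dict[int, set[int]] = {}
    rev_linked: dict[int, set[int]] = {}
    for i, j in graph.edges:
        linked.setdefault(i, set()).add(j)
        rev_linked.setdefault(j, set()).add(i)

    edges = np.array(sorted(graph.edges), dtype=np.int64)
    n_edges = len(edges)
    adam = _Adam([Ed.shape, Eg.shape], cfg.learning_rate)
    log: list[dict] = []
    components: dict = {}

    use_main_prop = cfg.variant != "mf"
    clean_op = SparseOp(graph.A_norm)

    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n_edges)
        acc = {"L_r": 0.0, "L_s_d": 0.0, "L_s_g": 0.0, "L2": 0.0, "total": 0.0}
        for start in range(0, n_edges, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            a = edges[idx, 0]
            p = edges[idx, 1]
            N = _fast_negatives(linked, graph.n, a, cfg.neg_per_pos, rng)
            batch = TrainBatch(
                anchor_drugs=a,
                pos_genes=p,
                neg_genes=N,
                cl_active_drugs=_draw_active_mask(graph.m, a, cfg.cl_keep_prob, rng),
                cl_active_genes=_draw_active_mask(graph.n, p, cfg.cl_keep_prob, rng),
            )
            if use_main_prop:
                if cfg.edge_dropout > 0:
                    main_ops: list[PropagationOp] = [
                        SparseOp(drop_edges(graph.A_norm, cfg.edge_dropout, rng)) for _ in range(cfg.L)
                    ]
                else:
                    main_ops = [clean_op] * cfg.L
            else:
                main_ops = []
            aug_ops = build_aug_ops(cfg.variant, graph, cfg, rng, svd_view)
            total, comps, dEd, dEg = batch_loss_and_grad(
                Ed, Eg, main_ops, aug_ops, batch, loss_cfg, activation=cfg.activation
            )
            if not np.isfinite(total):
                bad = [k for k, v in comps.items() if not np.isfinite(v)]
                raise RuntimeError(f"non-finite loss at epoch {epoch}: offending component(s) {bad or ['total']}")
            if cfg.gene_anchors:
                sym_total, sym_comps, sdEd, sdEg = _gene_anchor_pass(
                    Ed, Eg, main_ops, p, a, rev_linked, graph.m, cfg, loss_cfg, rng
                )
                total += sym_total
                comps["L_r"] += sym_comps["L_r"]
                dEd = dEd + sdEd
                dEg = dEg + sdEg
            Ed, Eg = adam.step([Ed, Eg], [dEd, dEg])
            for k in ("L_r", "L_s_d", "L_s_g", "L2"):
                acc[k] += comps[k]
            acc["total"] += total
        components = dict(acc)
        log.append({"epoch": epoch, **acc})

    ckpt = Checkpoint(
        config=cfg, E_drug=Ed, E_gene=Eg, svd_view=svd_view, epoch=cfg.epochs, loss_components=components
    )
    return ckpt, log


def _fast_negatives(linked: dict[int, set[int]], n: int, anchors: np.ndarray, S: int, rng) -> np.ndarray:
    """Uniform unobserved-gene draws per anchor using a prebuilt adjacency map."""
    out = np.empty((len(anchors), S), dtype=np.int64)
    draws = rng.integers(0, n, size=(len(anchors), S))
    for row, a in enumerate(anchors):
        known = linked.get(int(a), ())
        if len(known) >= n:
            raise ValueError(f"drug index {a} is associated with all genes")
        for s in range(S):
            j = int(draws[row, s])
            while j in known:
                j = int(rng.integers(0, n))
            out[row, s] = j
    return out


def _gene_anchor_pass(Ed, Eg, main_ops, gene_anchors, pos_drugs, rev_linked, m, cfg, loss_cfg, rng):
    """Optional symmetric hinge pass with genes as anchors (off by default)."""
    N_drugs = _fast_negatives(rev_linked, m, gene_anchors, cfg.neg_per_pos, rng)
    sigma, dsigma = get_activation(cfg.activation)
    Zd, Zg, Md, Mg = _chain_forward(Ed, Eg, main_ops, sigma)
    ed = sum(Zd[1:], Zd[0].copy())
    eg = sum(Zg[1:], Zg[0].copy())
    pos_scores = np.einsum("id,id->i", eg[gene_anchors], ed[pos_drugs])
    neg_scores = np.einsum("id,isd->is", eg[gene_anchors], ed[N_drugs])
    L_r, d_pos, d_neg = pairwise_hinge_grad(pos_scores, neg_scores)
    ded = np.zeros_like(ed)
    deg = np.zeros_like(eg)
    d = ed.shape[1]
    np.add.at(deg, gene_anchors, d_pos[:, None] * ed[pos_drugs] + np.einsum("is,isd->id", d_neg, ed[N_drugs]))
    np.add.at(ded, pos_drugs, d_pos[:, None] * eg[gene_anchors])
    np.add.at(ded, N_drugs.ravel(), (d_neg[:, :, None] * eg[gene_anchors][:, None, :]).reshape(-1, d))
    dZd_list = [ded.copy() for _ in Zd]
    dZg_list = [deg.copy() for _ in Zg]
    dEd, dEg = _chain_backward(dZd_list, dZg_list, Md, Mg, main_ops, dsigma)
    return L_r, {"L_r": L_r}, dEd, dEg


def compute_final_embeddings(ckpt: Checkpoint, graph: BipartiteGraph) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode final (layer-summed) embeddings for scoring.

    For the matrix-factorization variant the base embeddings are the final
    embeddings; all other variants propagate over the clean observed view.
    """
    if ckpt.config.variant == "mf":
        return ckpt.E_drug, ckpt.E_gene
    state = EmbeddingState(E_drug=ckpt.E_drug, E_gene=ckpt.E_gene)
    state.main_layers_drug = [ckpt.E_drug]
    state.main_layers_gene = [ckpt.E_gene]
    encode(graph, state, L=ckpt.config.L, edge_dropout=0.0, activation=ckpt.config.activation, mode="eval")
    return state.final_drug, state.final_gene


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    """Versioned on-disk checkpoint (NumPy archive + JSON header)."""
    arrays = {
        "version": np.array([CHECKPOINT_VERSION]),
        "config_json": np.frombuffer(json.dumps(asdict(ckpt.config)).encode(), dtype=np.uint8),
        "loss_json": np.frombuffer(json.dumps(ckpt.loss_components).encode(), dtype=np.uint8),
        "E_drug": ckpt.E_drug,
        "E_gene": ckpt.E_gene,
        "epoch": np.array([ckpt.epoch]),
    }
    if ckpt.svd_view is not None:
        arrays["svd_U"] = ckpt.svd_view.U_t
        arrays["svd_s"] = ckpt.svd_view.s
        arrays["svd_V"] = ckpt.svd_view.V_t
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path, expect_config: TrainConfig | None = None) -> Checkpoint:
    """Load a checkpoint; fails loudly on corruption or schema mismatch."""
    try:
        with np.load(path, allow_pickle=False) as data:
            if "version" not in data:
                raise ValueError(f"{path}: not a checkpoint (missing version header)")
            version = int(data["version"][0])
            if version != CHECKPOINT_VERSION:
                raise ValueError(f"{path}: checkpoint version {version} != supported {CHECKPOINT_VERSION}")
            cfg = TrainConfig(**json.loads(bytes(data["config_json"]).decode()))
            loss = json.loads(bytes(data["loss_json"]).decode())
            svd_view = None
            if "svd_U" in data:
                svd_view = SVDView(U_t=data["svd_U"], s=data["svd_s"], V_t=data["svd_V"])
            ckpt = Checkpoint(
                config=cfg,
                E_drug=data["E_drug"],
                E_gene=data["E_gene"],
                svd_view=svd_view,
                epoch=int(data["epoch"][0]),
                loss_components=loss,
            )
    except (zipfile.BadZipFile, OSError, KeyError) as exc:
        raise ValueError(f"{path}: corrupt or truncated checkpoint ({exc})") from exc
    if expect_config is not None and expect_config.d != ckpt.config.d:
        raise ValueError(f"embedding width mismatch: checkpoint d={ckpt.config.d}, requested d={expect_config.d}")
    return ckpt
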