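"""Desk-scale experiment suite on synthetic planted-block graphs.

Stands in for database-scale benchmarking: an ablation table comparing the
contrastive variants on shared splits/seeds, and parameter-sensitivity sweeps
over embedding width and layer count.  Suite defaults train 50 epochs on the
default synthetic graph (100 drugs x 60 genes, 4 planted blocks), which keeps
a full ablation run in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import evaluate_fold
from .graph_io import BipartiteGraph, SyntheticSpec, generate_synthetic_graph, make_cv_folds
from .trainer import VARIANTS, TrainConfig, train

__all__ = [
    "ExperimentGrid",
    "default_synthetic_spec",
    "default_suite_config",
    "holdout_auc",
    "run_ablation_suite",
    "run_sensitivity_sweep",
]

SWEEP_VALUES = {"d": [64, 128, 256, 512, 1024], "L": [1, 2, 3, 4]}


@dataclass
class ExperimentGrid:
    """A one-parameter sweep: which knob, which values, which seeds."""

    sweep_parameter: str
    values: list = field(default_factory=list)
    seeds: list[int] = field(default_factory=lambda: [0])
    base_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.sweep_parameter not in SWEEP_VALUES:
            raise ValueError(f"sweep_parameter must be one of {sorted(SWEEP_VALUES)}")
        if not self.values:
            self.values = list(SWEEP_VALUES[self.sweep_parameter])
        if not self.values or not self.seeds:
            raise ValueError("values and seeds must be non-empty")


def default_synthetic_spec(seed: int = 0) -> SyntheticSpec:
    """The package's standard desk-scale fixture graph."""
    return SyntheticSpec(m=100, n=60, n_blocks=4, p_in=0.3, p_out=0.02, seed=seed)


def default_suite_config(**overrides) -> TrainConfig:
    """Suite training defaults: 50 epochs on synthetic fixtures."""
    base = dict(epochs=50)
    base.update(overrides)
    return TrainConfig(**base)


def holdout_auc(
    graph: BipartiteGraph,
    cfg: TrainConfig,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> float:
    """Train once with a fraction of edges held out and return test AUC."""
    k = max(2, int(round(1.0 / holdout_fraction)))
    fold = make_cv_folds(graph, k=k, seed=seed)[0]
    train_graph = graph.subgraph_with_edges(fold.train_edges)
    ckpt, _ = train(train_graph, replace(cfg, seed=seed))
    return evaluate_fold(ckpt, graph, fold).auc


def run_ablation_suite(
    graph: BipartiteGraph,
    base_config: TrainConfig,
    seeds: list[int],
    variants: tuple[str, ...] = ("full", "gcn_none", "gcn_ed", "gcn_nd", "gcn_rw"),
) -> pd.DataFrame:
    """Variant x metric table of held-out means over shared splits/seeds.

    For each seed, one 20% edge holdout is drawn once and reused by every
    variant, so rows differ only in the augmentation strategy.
    """
    if len(variants) < 2:
        raise ValueError("ablation needs at least 2 variants")
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    rows: dict[str, list[dict]] = {v: [] for v in variants}
    for seed in seeds:
        fold = make_cv_folds(graph, k=5, seed=seed)[0]
        train_graph = graph.subgraph_with_edges(fold.train_edges)
        for variant in variants:
            cfg = replace(base_config, variant=variant, seed=seed)
            ckpt, _ = train(train_graph, cfg)
            rows[variant].append(evaluate_fold(ckpt, graph, fold).as_dict())
    records = []
    for variant in variants:
        df = pd.DataFrame(rows[variant])
        records.append({"variant": variant, **df.mean().to_dict(), "n_seeds": len(seeds)})
    return pd.DataFrame(records)


def run_sensitivity_sweep(graph: BipartiteGraph, grid: ExperimentGrid) -> pd.DataFrame:
    """Value x metric table for a single-parameter sweep (d or L)."""
    records = []
    for value in grid.values:
        per_seed = []
        for seed in grid.seeds:
            fold = make_cv_folds(graph, k=5, seed=seed)[0]
            train_graph = graph.subgraph_with_edges(fold.train_edges)
            cfg = replace(grid.base_config, seed=seed, **{grid.sweep_parameter: value})
            ckpt, _ = train(train_graph, cfg)
            per_seed.append(evaluate_fold(ckpt, graph, fold).as_dict())
        df = pd.DataFrame(per_seed)
        records.append({grid.sweep_parameter: value, **df.mean().to_dict(), "n_seeds": len(grid.seeds)})
    return pd.DataFrame(records)
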