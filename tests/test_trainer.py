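"""Training loop, ablation variants, and checkpoint round-trips."""

import numpy as np
import pytest

from svdgcl.gcn_encoder import drop_edges, encode, init_embeddings
from svdgcl.svd_augmentation import truncated_randomized_svd
from svdgcl.trainer import (
    Checkpoint,
    TrainConfig,
    load_checkpoint,
    make_variant_view,
    save_checkpoint,
    train,
)
from svdgcl.evaluation import score_pairs
from svdgcl.trainer import compute_final_embeddings


def small_cfg(**kw):
    base = dict(d=16, L=2, t=3, epochs=5, batch_size=64, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainConfig:
    def test_defaults_match_model_settings(self):
        cfg = TrainConfig()
        assert (cfg.d, cfg.L, cfg.epochs) == (256, 2, 300)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            TrainConfig(variant="nope")

    def test_yaml_round_trip_with_overrides(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("d: 32\nepochs: 7\nvariant: gcn_ed\n")
        cfg = TrainConfig.from_file(path, epochs=9)
        assert (cfg.d, cfg.epochs, cfg.variant) == (32, 9, "gcn_ed")

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("embedding: 32\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            TrainConfig.from_file(path)


class TestTrainLoop:
    def test_zero_epochs_equals_initialization(self, tiny_graph):
        cfg = small_cfg(epochs=0)
        ckpt, log = train(tiny_graph, cfg)
        init = init_embeddings(tiny_graph.m, tiny_graph.n, cfg.d, seed=cfg.seed)
        np.testing.assert_array_equal(ckpt.E_drug, init.E_drug)
        np.testing.assert_array_equal(ckpt.E_gene, init.E_gene)
        assert log == []

    def test_seed_determinism(self, tiny_graph):
        a, _ = train(tiny_graph, small_cfg(epochs=4))
        b, _ = train(tiny_graph, small_cfg(epochs=4))
        np.testing.assert_allclose(a.E_drug, b.E_drug, atol=1e-12)
        np.testing.assert_allclose(a.E_gene, b.E_gene, atol=1e-12)

    def test_loss_decreases_over_training(self, synth_graph):
        graph, _, _ = synth_graph
        wins = 0
        for seed in range(3):
            _, log = train(graph, small_cfg(d=32, epochs=50, batch_size=1024, seed=seed))
            if log[-1]["total"] < log[0]["total"]:
                wins += 1
        assert wins == 3

    def test_log_has_all_components(self, tiny_graph):
        _, log = train(tiny_graph, small_cfg(epochs=2))
        assert {"epoch", "L_r", "L_s_d", "L_s_g", "L2", "total"} <= set(log[0])

    def test_gcn_none_contrastive_term_identically_zero(self, tiny_graph):
        _, log = train(tiny_graph, small_cfg(epochs=4, variant="gcn_none"))
        assert all(row["L_s_d"] == 0.0 and row["L_s_g"] == 0.0 for row in log)

    def test_graph_not_mutated_by_training(self, tiny_graph):
        edges_before = set(tiny_graph.edges)
        data_before = tiny_graph.A_norm.toarray().copy()
        train(tiny_graph, small_cfg(epochs=3))
        assert tiny_graph.edges == edges_before
        np.testing.assert_array_equal(tiny_graph.A_norm.toarray(), data_before)

    def test_empty_graph_rejected(self, tiny_graph):
        bare = tiny_graph.subgraph_with_edges(set())
        with pytest.raises(ValueError):
            train(bare, small_cfg())

    def test_nonfinite_loss_aborts_with_diagnostic(self, tiny_graph):
        # an absurd learning rate overflows the embeddings within a few steps
        cfg = small_cfg(epochs=10, learning_rate=1e160)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(RuntimeError, match="non-finite"):
                train(tiny_graph, cfg)


class TestVariantViews:
    def test_full_dispatch_matches_encode_augmented(self, tiny_graph):
        from svdgcl.svd_augmentation import encode_augmented

        cfg = small_cfg()
        state = init_embeddings(tiny_graph.m, tiny_graph.n, cfg.d, seed=0)
        view = truncated_randomized_svd(tiny_graph.A_norm, t=cfg.t, seed=0)
        Hd, Hg = make_variant_view("full", tiny_graph, state, cfg, np.random.default_rng(0), svd_view=view)
        ref = init_embeddings(tiny_graph.m, tiny_graph.n, cfg.d, seed=0)
        encode_augmented(view, ref, L=cfg.L, activation=cfg.activation)
        for a, b in zip(Hd, ref.aug_layers_drug):
            np.testing.assert_allclose(a, b, atol=1e-12)
        for a, b in zip(Hg, ref.aug_layers_gene):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_node_drop_rate_zero_equals_clean_propagation(self, tiny_graph):
        cfg = small_cfg(node_drop_rate=0.0)
        state = init_embeddings(tiny_graph.m, tiny_graph.n, cfg.d, seed=1)
        Hd, Hg = make_variant_view("gcn_nd", tiny_graph, state, cfg, np.random.default_rng(0))
        ref = init_embeddings(tiny_graph.m, tiny_graph.n, cfg.d, seed=1)
        encode(tiny_graph, ref, L=cfg.L, edge_dropout=0.0, activation=cfg.activation, mode="eval")
        np.testing.assert_allclose(Hd[-1], ref.main_layers_drug[-1], atol=1e-10)
        np.testing.assert_allclose(Hg[-1], ref.main_layers_gene[-1], atol=1e-10)

    def test_edge_perturbation_kept_count_binomial(self, tiny_graph):
        rate = 0.25
        rng = np.random.default_rng(0)
        nnz = tiny_graph.A_norm.nnz
        kept = np.array([drop_edges(tiny_graph.A_norm, rate, rng).nnz for _ in range(1000)])
        expected = (1 - rate) * nnz
        se = np.sqrt(nnz * rate * (1 - rate)) / np.sqrt(1000)
        assert abs(kept.mean() - expected) <= 3 * np.sqrt(nnz * rate * (1 - rate)) / np.sqrt(1000) + 3 * se

    def test_random_walk_view_uses_fresh_masks_per_layer(self, tiny_graph):
        from svdgcl.trainer import build_aug_ops

        cfg = small_cfg(edge_dropout=0.5)
        ops = build_aug_ops("gcn_rw", tiny_graph, cfg, np.random.default_rng(3))
        assert len(ops) == cfg.L
        patterns = [tuple(map(tuple, np.argwhere(op.P.toarray() != 0))) for op in ops]
        assert patterns[0] != patterns[1]  # overwhelmingly likely at 50% drop

    def test_variants_without_augmented_view_rejected(self, tiny_graph):
        cfg = small_cfg()
        state = init_embeddings(tiny_graph.m, tiny_graph.n, cfg.d, seed=0)
        for variant in ("gcn_none", "mf"):
            with pytest.raises(ValueError):
                make_variant_view(variant, tiny_graph, state, cfg, np.random.default_rng(0))

    def test_all_variants_train_and_score(self, tiny_graph):
        for variant in ("full", "gcn_none", "gcn_ed", "gcn_nd", "gcn_rw", "mf"):
            ckpt, _ = train(tiny_graph, small_cfg(epochs=2, variant=variant))
            e_d, e_g = compute_final_embeddings(ckpt, tiny_graph)
            scores = score_pairs(e_d, e_g, sorted(tiny_graph.edges))
            assert np.all(np.isfinite(scores))


class TestCheckpoint:
    def test_round_trip_preserves_probe_scores(self, tiny_graph, tmp_path):
        ckpt, _ = train(tiny_graph, small_cfg(epochs=3))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(ckpt, path)
        loaded = load_checkpoint(path)
        probe = sorted(tiny_graph.edges)
        e1 = compute_final_embeddings(ckpt, tiny_graph)
        e2 = compute_final_embeddings(loaded, tiny_graph)
        np.testing.assert_array_equal(score_pairs(*e1, probe), score_pairs(*e2, probe))
        assert loaded.config == ckpt.config

    def test_truncated_file_raises_not_corrupts(self, tiny_graph, tmp_path):
        ckpt, _ = train(tiny_graph, small_cfg(epochs=1))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(ckpt, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="corrupt|truncated"):
            load_checkpoint(path)

    def test_width_mismatch_named_in_error(self, tiny_graph, tmp_path):
        ckpt, _ = train(tiny_graph, small_cfg(epochs=1, d=16))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(ckpt, path)
        with pytest.raises(ValueError, match="width mismatch"):
            load_checkpoint(path, expect_config=small_cfg(d=32))
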