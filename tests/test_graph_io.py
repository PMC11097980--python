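"""Edge-list parsing, degree normalization, CV splitting, and the generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svdgcl.graph_io import (
    SyntheticSpec,
    build_graph,
    generate_synthetic_graph,
    graph_summary,
    load_edge_list,
    make_cv_folds,
    normalize_adjacency,
    sample_non_edges,
)


def write_tsv(tmp_path, rows, name="edges.tsv"):
    path = tmp_path / name
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n")
    return path


class TestLoadEdgeList:
    def test_counts_and_first_appearance_order(self, tmp_path):
        path = write_tsv(tmp_path, [("D1", "G1"), ("D1", "G2"), ("D2", "G1")])
        g = load_edge_list(path)
        assert (g.m, g.n, g.n_edges) == (2, 2, 3)
        assert g.drug_ids == ["D1", "D2"] and g.gene_ids == ["G1", "G2"]

    def test_duplicate_rows_collapse(self, tmp_path):
        path = write_tsv(tmp_path, [("D1", "G1"), ("D1", "G1")])
        assert load_edge_list(path).n_edges == 1

    def test_matches_hand_built_incidence(self, tmp_path):
        rows = [(f"D{i % 5}", f"G{(i * 3) % 7}") for i in range(20)]
        path = write_tsv(tmp_path, rows)
        g = load_edge_list(path)
        # independent dict-of-sets walk over the same rows
        drugs, genes, assoc = [], [], {}
        for d, gg in rows:
            if d not in drugs:
                drugs.append(d)
            if gg not in genes:
                genes.append(gg)
            assoc.setdefault(d, set()).add(gg)
        expected = np.zeros((len(drugs), len(genes)))
        for d, gs in assoc.items():
            for gg in gs:
                expected[drugs.index(d), genes.index(gg)] = 1
        np.testing.assert_array_equal(g.A.toarray(), expected)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="no associations"):
            load_edge_list(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("D1\tG1\njust-one-field\n")
        with pytest.raises(ValueError, match="line 2"):
            load_edge_list(path)

    def test_header_flag_skips_first_line(self, tmp_path):
        path = write_tsv(tmp_path, [("drug_id", "gene_id"), ("D1", "G1")])
        g = load_edge_list(path, header=True)
        assert g.n_edges == 1 and g.drug_ids == ["D1"]


class TestNormalizeAdjacency:
    def test_single_entry(self):
        out = normalize_adjacency(np.array([[1.0]]))
        np.testing.assert_allclose(out.toarray(), [[1.0]])

    def test_hand_computed_two_by_two(self):
        A = np.array([[1, 1], [0, 1]], dtype=float)
        expected = np.array([[1 / np.sqrt(2), 0.5], [0.0, 1 / np.sqrt(2)]])
        np.testing.assert_allclose(normalize_adjacency(A).toarray(), expected, atol=1e-12)

    def test_zero_row_stays_zero_without_nan(self):
        A = np.array([[1, 0], [0, 0]], dtype=float)
        out = normalize_adjacency(A).toarray()
        assert np.all(np.isfinite(out)) and np.all(out[1] == 0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_entries_in_unit_interval_and_support_preserved(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((7, 5)) < 0.4).astype(float)
        out = normalize_adjacency(A).toarray()
        assert out.min() >= 0 and out.max() <= 1
        np.testing.assert_array_equal(out > 0, A > 0)


class TestCvFolds:
    def _ten_edge_graph(self):
        edges = {(i, i % 4) for i in range(8)} | {(0, 3), (1, 3)}
        return build_graph([f"D{i}" for i in range(8)], [f"G{j}" for j in range(4)], edges)

    def test_partition_contract(self):
        g = self._ten_edge_graph()
        folds = make_cv_folds(g, k=5, seed=1)
        tests = [f.test_edges for f in folds]
        assert all(len(t) == 2 for t in tests)
        union = set().union(*tests)
        assert union == g.edges
        assert sum(len(t) for t in tests) == g.n_edges  # pairwise disjoint
        for f in folds:
            assert f.train_edges | f.test_edges == g.edges
            assert not (f.train_edges & f.test_edges)
            assert not (f.test_negatives & g.edges)
            assert len(f.test_negatives) == len(f.test_edges)

    def test_same_seed_identical_folds(self):
        g = self._ten_edge_graph()
        a = make_cv_folds(g, k=5, seed=7)
        b = make_cv_folds(g, k=5, seed=7)
        for fa, fb in zip(a, b):
            assert fa.test_edges == fb.test_edges and fa.test_negatives == fb.test_negatives

    def test_fold_sizes_at_database_scale(self):
        # 46 892 edges into 5 folds: sizes in {9378, 9379} with 9379 twice
        rng = np.random.default_rng(0)
        m, n = 500, 200
        flat = rng.choice(m * n, size=46892, replace=False)
        edges = {(int(f // n), int(f % n)) for f in flat}
        g = build_graph([f"D{i}" for i in range(m)], [f"G{j}" for j in range(n)], edges)
        folds = make_cv_folds(g, k=5, neg_ratio=0.0, seed=0)
        sizes = sorted(len(f.test_edges) for f in folds)
        assert sizes == [9378, 9378, 9378, 9379, 9379]

    def test_k_larger_than_edges_errors(self):
        g = self._ten_edge_graph()
        with pytest.raises(ValueError, match="exceeds"):
            make_cv_folds(g, k=11)

    def test_negative_pool_exhaustion_errors(self):
        # nearly complete bipartite graph: not enough non-edges for negatives
        edges = {(i, j) for i in range(3) for j in range(3)} - {(2, 2)}
        g = build_graph(["a", "b", "c"], ["x", "y", "z"], edges)
        with pytest.raises(ValueError, match="non-edges"):
            make_cv_folds(g, k=4, neg_ratio=2.0, seed=0)

    def test_sample_non_edges_avoids_edges(self, rng):
        g = self._ten_edge_graph()
        neg = sample_non_edges(g, 10, rng)
        assert len(neg) == 10 and not (neg & g.edges)


class TestSyntheticGenerator:
    def test_deterministic_limit(self):
        g, db, gb = generate_synthetic_graph(SyntheticSpec(m=8, n=6, n_blocks=2, p_in=1.0, p_out=0.0, seed=0))
        expected = {(i, j) for i in range(8) for j in range(6) if db[i] == gb[j]}
        assert g.edges == expected

    def test_edge_count_within_binomial_band(self):
        spec = SyntheticSpec(m=100, n=60, n_blocks=4, p_in=0.3, p_out=0.02, seed=5)
        g, db, gb = generate_synthetic_graph(spec)
        same = (db[:, None] == gb[None, :])
        n_in, n_out = int(same.sum()), int((~same).sum())
        mean = n_in * spec.p_in + n_out * spec.p_out
        var = n_in * spec.p_in * (1 - spec.p_in) + n_out * spec.p_out * (1 - spec.p_out)
        assert abs(g.n_edges - mean) <= 4 * np.sqrt(var)

    def test_different_seeds_differ(self):
        g1, _, _ = generate_synthetic_graph(SyntheticSpec(seed=1))
        g2, _, _ = generate_synthetic_graph(SyntheticSpec(seed=2))
        assert g1.edges != g2.edges

    def test_zero_edge_draw_errors(self):
        with pytest.raises(ValueError, match="zero edges"):
            generate_synthetic_graph(SyntheticSpec(m=5, n=5, n_blocks=2, p_in=1e-9, p_out=0.0, seed=0))

    def test_within_block_frequency_converges_to_p_in(self):
        spec = SyntheticSpec(m=400, n=400, n_blocks=4, p_in=0.3, p_out=0.02, seed=11)
        g, db, gb = generate_synthetic_graph(spec)
        same = db[:, None] == gb[None, :]
        freq = g.A.toarray()[same].mean()
        assert abs(freq - spec.p_in) <= 0.02

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(p_in=0.1, p_out=0.2)
        with pytest.raises(ValueError):
            SyntheticSpec(m=3, n=3, n_blocks=5)


def test_graph_summary_fields(tiny_graph):
    s = graph_summary(tiny_graph)
    assert s["n_drugs"] == 6 and s["n_genes"] == 4 and s["n_edges"] == 9
    assert s["density"] == pytest.approx(9 / 24)
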