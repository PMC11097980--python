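import numpy as np
import pytest

from svdgcl.graph_io import BipartiteGraph, SyntheticSpec, build_graph, generate_synthetic_graph


@pytest.fixture
def tiny_graph() -> BipartiteGraph:
    """6 drugs x 4 genes, hand-picked edges touching every node."""
    edges = {(0, 0), (0, 1), (1, 1), (2, 2), (2, 3), (3, 0), (4, 2), (5, 3), (1, 2)}
    return build_graph([f"D{i}" for i in range(6)], [f"G{j}" for j in range(4)], edges)


@pytest.fixture(scope="session")
def synth_graph():
    """The default planted-block fixture graph (100 drugs x 60 genes, 4 blocks)."""
    graph, drug_blocks, gene_blocks = generate_synthetic_graph(
        SyntheticSpec(m=100, n=60, n_blocks=4, p_in=0.3, p_out=0.02, seed=0)
    )
    return graph, drug_blocks, gene_blocks


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
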