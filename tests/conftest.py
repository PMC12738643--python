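import numpy as np
import pytest

from hdti.chem_graph import smiles_to_graph


def random_symmetric_graph(rng, max_nodes=8, d=5):
    """Random small graph with symmetric directed edges (molecule-like)."""
    n = int(rng.integers(2, max_nodes + 1))
    H = rng.normal(size=(n, d))
    pairs = [(u, v) for u in range(n) for v in range(u + 1, n)
             if rng.random() < 0.5]
    if not pairs:
        pairs = [(0, 1)]
    src = [u for u, v in pairs] + [v for u, v in pairs]
    dst = [v for u, v in pairs] + [u for u, v in pairs]
    edge_index = np.asarray([src, dst], dtype=np.int64)
    return H, edge_index


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benzene():
    return smiles_to_graph("c1ccccc1")


@pytest.fixture(scope="session")
def toy_graphs():
    smiles = ["CCO", "c1ccccc1", "CC(=O)O", "CCN(CC)CC", "C1CCCCC1O"]
    return [smiles_to_graph(s) for s in smiles]
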