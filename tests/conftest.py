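import networkx as nx
import pytest

from nettopo import generators


def random_clean_graph(seed: int, max_nodes: int = 30) -> nx.Graph:
    """A seeded random simple graph with string labels, size <= max_nodes."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.5))
    return generators.generate_erdos_renyi(n, p, seed=seed + 1)


@pytest.fixture(scope="session")
def fixtures():
    return generators.fixture_suite()


@pytest.fixture(scope="session")
def ba_128():
    return generators.generate_barabasi_albert(128, 2, seed=7)


@pytest.fixture(scope="session")
def hier_3():
    return generators.generate_hierarchical(3, seed=7)
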