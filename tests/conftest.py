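from itertools import combinations

import numpy as np
import pytest

from hypermet import Hyperedge, Hypergraph, toy_fixtures


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


def random_hypergraph(rng: np.random.Generator, max_nodes: int = 8, max_edges: int = 5,
                      min_card: int = 2, max_card: int = 4) -> Hypergraph:
    """Small random undirected hypergraph for oracle comparisons."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    candidates = [
        c for k in range(min_card, min(n, max_card) + 1) for c in combinations(nodes, k)
    ]
    m = int(rng.integers(1, min(max_edges, len(candidates)) + 1))
    idx = rng.choice(len(candidates), size=m, replace=False)
    edges = [Hyperedge.undirected(candidates[i]) for i in sorted(int(j) for j in idx)]
    return Hypergraph(nodes, edges)
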