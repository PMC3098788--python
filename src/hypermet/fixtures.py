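"""Deterministic toy hypergraphs used across examples and tests.

All fixtures are at reaction-diagram scale (at most 8 nodes, 4
hyperedges) and validate the full set of structural invariants at
construction time.
"""

from __future__ import annotations

from .core import Hyperedge, Hypergraph

__all__ = ["toy_fixtures"]


def toy_fixtures() -> dict[str, Hypergraph]:
    """Named toy instances.

    - ``one-reaction``: a single directed reaction A + B -> C + D; its
      primal is K4 (6 edges), cis-primal has 2 edges, trans-primal 4.
    - ``shared-reactant``: two directed reactions sharing the reactant
      D, so their reaction graph (PLGT) has exactly one edge.
    - ``triangle``: the cardinality-2 triangle, a standard graph in
      hypergraph form.
    - ``mixed``: mixed cardinalities 2-4 with one shared metabolite
      chain, exercising overlaps between hyperedges of unequal size.
    """
    fixtures: dict[str, Hypergraph] = {}

    fixtures["one-reaction"] = Hypergraph(
        ["A", "B", "C", "D"],
        [Hyperedge.directed(["A", "B"], ["C", "D"], id="R1")],
        directed=True,
    )

    fixtures["shared-reactant"] = Hypergraph(
        ["A", "B", "C", "D", "E"],
        [
            Hyperedge.directed(["A", "B"], ["D"], id="R1"),
            Hyperedge.directed(["C", "D"], ["E"], id="R2"),
        ],
        directed=True,
    )

    fixtures["triangle"] = Hypergraph(
        ["A", "B", "C"],
        [
            Hyperedge.undirected(["A", "B"], id="E1"),
            Hyperedge.undirected(["B", "C"], id="E2"),
            Hyperedge.undirected(["A", "C"], id="E3"),
        ],
    )

    fixtures["mixed"] = Hypergraph(
        ["A", "B", "C", "D", "E", "F", "G"],
        [
            Hyperedge.undirected(["A", "B", "C"], id="E1"),
            Hyperedge.undirected(["C", "D"], id="E2"),
            Hyperedge.undirected(["D", "E", "F", "G"], id="E3"),
            Hyperedge.undirected(["A", "G"], id="E4"),
        ],
    )

    return fixtures
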