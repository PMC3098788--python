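"""Hypergraph-to-standard-graph abstractions.

Metabolic standard graphs in the literature are abstractions of the
underlying reaction hypergraph:

* ``primal`` -- the "substance model": every pair of metabolites sharing
  a reaction is linked, so each hyperedge becomes a clique.
* ``cis_primal`` -- the "substrate-substrate model": only same-side
  pairs of a directed reaction are linked.
* ``trans_primal`` -- the "substrate-product model": only opposite-side
  pairs are linked.
* ``plgt`` -- the physical line graph transformation, i.e. the reaction
  graph: primal of the dual; two reactions are adjacent iff they share a
  reactant.
* ``union_transform`` -- the enzyme/gene hypergraph: each output
  hyperedge is the union of the reactions catalysed by one enzyme/gene.

All abstractions emit simple graphs (self-loops impossible, duplicate
pairs collapsed) and keep the full node set, so nodes isolated by an
abstraction remain with degree 0.
"""

from __future__ import annotations

from itertools import combinations
from typing import Collection, Iterable

from .core import Hyperedge, Hypergraph, HypergraphError, SimpleGraph, dual

__all__ = ["primal", "cis_primal", "trans_primal", "plgt", "union_transform"]


def primal(H: Hypergraph) -> SimpleGraph:
    """G_p: link every pair of nodes that co-occur in a hyperedge.

    Directed hyperedges are flattened (tail | head) first; each
    hyperedge of cardinality k contributes a k-clique, and duplicate
    pairs across hyperedges collapse into one edge.
    """
    edges: set[tuple[str, str]] = set()
    for e in H.hyperedges:
        for u, w in combinations(e.members, 2):  # members sorted, so u < w
            edges.add((u, w))
    return SimpleGraph(H.nodes, edges)


def cis_primal(H: Hypergraph) -> SimpleGraph:
    """G_cp: link every same-side pair (both in tail, or both in head)."""
    if not H.directed:
        raise HypergraphError(
            "cis-primal requires a directed hypergraph (a tail/head bipartition)"
        )
    edges: set[tuple[str, str]] = set()
    for e in H.hyperedges:
        for side in (e.tail, e.head):
            for u, w in combinations(side, 2):
                edges.add((u, w))
    return SimpleGraph(H.nodes, edges)


def trans_primal(H: Hypergraph) -> SimpleGraph:
    """G_tp: link every opposite-side pair (one in tail, one in head)."""
    if not H.directed:
        raise HypergraphError(
            "trans-primal requires a directed hypergraph (a tail/head bipartition)"
        )
    edges: set[tuple[str, str]] = set()
    for e in H.hyperedges:
        for u in e.tail:
            for w in e.head:
                edges.add((u, w) if u < w else (w, u))
    return SimpleGraph(H.nodes, edges)


def plgt(H: Hypergraph) -> SimpleGraph:
    """Physical line graph transformation: primal of the dual of H.

    Nodes are H's hyperedges (reactions); two reactions are adjacent iff
    they share at least one reactant of hyper-degree >= 2.  A metabolite
    participating in k reactions contributes a k-clique, i.e.
    k(k-1)/2 reaction pairs.
    """
    return primal(dual(H, on_low_degree="drop"))


def union_transform(H: Hypergraph, groups: Collection[Iterable[str]]) -> Hypergraph:
    """Enzyme/gene hypergraph: one hyperedge per group of reactions.

    Each group is a collection of hyperedge ids; the output hyperedge is
    the union of the member hyperedges' node sets.  Because several
    enzymes/genes may catalyse overlapping or identical reaction sets,
    resulting hyperedges may coincide; they are retained with distinct
    ids and the output is flagged as allowing duplicates.
    """
    if not groups:
        raise HypergraphError("union_transform requires at least one group")
    out_edges: list[Hyperedge] = []
    for i, group in enumerate(groups):
        ids = list(group)
        if not ids:
            raise HypergraphError(f"group {i} is empty")
        members: set[str] = set()
        for eid in ids:
            members.update(H.edge_by_id(eid).members)
        out_edges.append(Hyperedge.undirected(members, id=f"U{i + 1}"))
    return Hypergraph(H.nodes, out_edges, directed=False, allow_duplicate_hyperedges=True)
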