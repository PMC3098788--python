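"""Hypergraph and simple-graph data model for metabolic networks.

A metabolic network's connectivity map is naturally a hypergraph
``H = (V, E)``: metabolites are nodes and each reaction is a hyperedge
connecting every species it involves.  A hyperedge is either an
undirected node subset of cardinality >= 2, or -- for a directed
hypergraph -- a bipartition into a non-empty *tail* (substrates) and a
non-empty *head* (products).  Reaction direction beyond this tail/head
split, stoichiometric coefficients and mass balance are deliberately not
modelled: the incidence structure alone is the object of study.

This module holds the structural primitives everything else builds on:
node degree, neighborhoods, the binary incidence matrix, the dual
hypergraph (transpose of the incidence matrix), node removal (used for
currency-metabolite experiments) and combinatorial sparsity bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HypergraphError",
    "Hyperedge",
    "Hypergraph",
    "SimpleGraph",
    "IncidenceMatrix",
    "hyper_degree",
    "neighborhood",
    "incidence_matrix",
    "dual",
    "remove_node",
    "max_distinct_hyperedges",
    "max_nontrivial_hyperedges",
]


class HypergraphError(ValueError):
    """Raised on any structural invariant violation."""


def _as_sorted_unique(items: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(set(items)))


@dataclass(frozen=True)
class Hyperedge:
    """A single hyperedge (reaction).

    ``members`` is the sorted tuple of all participating nodes.  For a
    directed hyperedge, ``tail`` and ``head`` are disjoint non-empty
    sorted tuples and ``members == sorted(tail + head)``; for an
    undirected hyperedge both are ``None``.
    """

    members: tuple[str, ...]
    tail: tuple[str, ...] | None = None
    head: tuple[str, ...] | None = None
    id: str | None = None

    @classmethod
    def undirected(cls, nodes: Iterable[str], id: str | None = None) -> "Hyperedge":
        members = _as_sorted_unique(nodes)
        if len(members) < 2:
            raise HypergraphError(
                f"hyperedge {id or members!r} has cardinality {len(members)} < 2"
            )
        return cls(members=members, id=id)

    @classmethod
    def directed(
        cls, tail: Iterable[str], head: Iterable[str], id: str | None = None
    ) -> "Hyperedge":
        t = _as_sorted_unique(tail)
        h = _as_sorted_unique(head)
        if not t or not h:
            raise HypergraphError(f"directed hyperedge {id!r}: tail and head must be non-empty")
        if set(t) & set(h):
            raise HypergraphError(
                f"directed hyperedge {id!r}: tail and head must be disjoint, "
                f"shared: {sorted(set(t) & set(h))}"
            )
        return cls(members=tuple(sorted(t + h)), tail=t, head=h, id=id)

    @property
    def is_directed(self) -> bool:
        return self.tail is not None

    @property
    def cardinality(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def key(self):
        """Identity of the hyperedge for distinctness checks."""
        if self.is_directed:
            return (frozenset(self.tail), frozenset(self.head))
        return frozenset(self.members)

    def with_id(self, id: str) -> "Hyperedge":
        return Hyperedge(members=self.members, tail=self.tail, head=self.head, id=id)


class Hypergraph:
    """A finite hypergraph ``H = (V, E)`` with deterministic ordering.

    Nodes and hyperedges keep insertion order; hyperedges without an id
    are labelled ``E1, E2, ...`` in order.  All hyperedges must be
    pairwise distinct (as node sets, or as (tail, head) pairs in the
    directed case) unless ``allow_duplicate_hyperedges`` is set, which
    is reserved for enzyme/gene union transforms where coinciding
    hyperedges are meaningful.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        hyperedges: Iterable[Hyperedge],
        directed: bool = False,
        allow_duplicate_hyperedges: bool = False,
    ) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise HypergraphError("duplicate node identifiers in node set")
        self.directed = bool(directed)
        self.allow_duplicate_hyperedges = bool(allow_duplicate_hyperedges)

        node_set = set(self.nodes)
        edges: list[Hyperedge] = []
        seen_keys: set = set()
        seen_ids: set[str] = set()
        for i, e in enumerate(hyperedges):
            if e.is_directed != self.directed:
                kind = "directed" if e.is_directed else "undirected"
                raise HypergraphError(
                    f"{kind} hyperedge {e.id or i} in a "
                    f"{'directed' if self.directed else 'undirected'} hypergraph"
                )
            missing = set(e.members) - node_set
            if missing:
                raise HypergraphError(
                    f"hyperedge {e.id or i} references unknown nodes {sorted(missing)}"
                )
            if e.id is None:
                e = e.with_id(f"E{i + 1}")
            if e.id in seen_ids:
                raise HypergraphError(f"duplicate hyperedge id {e.id!r}")
            seen_ids.add(e.id)
            k = e.key()
            if k in seen_keys and not self.allow_duplicate_hyperedges:
                raise HypergraphError(
                    f"duplicate hyperedge {e.id!r}: hyperedges must be pairwise distinct"
                )
            seen_keys.add(k)
            edges.append(e)
        self.hyperedges: tuple[Hyperedge, ...] = tuple(edges)
        self._by_id: dict[str, Hyperedge] = {e.id: e for e in self.hyperedges}
        # node -> indices of incident hyperedges, in hyperedge order
        inc: dict[str, list[int]] = {v: [] for v in self.nodes}
        for j, e in enumerate(self.hyperedges):
            for v in e.members:
                inc[v].append(j)
        self._incident: dict[str, tuple[int, ...]] = {v: tuple(js) for v, js in inc.items()}

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.nodes)

    @property
    def m(self) -> int:
        """Number of hyperedges."""
        return len(self.hyperedges)

    def cardinalities(self) -> tuple[int, ...]:
        return tuple(e.cardinality for e in self.hyperedges)

    def edge_by_id(self, edge_id: str) -> Hyperedge:
        try:
            return self._by_id[edge_id]
        except KeyError:
            raise HypergraphError(f"unknown hyperedge id {edge_id!r}") from None

    def has_node(self, v: str) -> bool:
        return v in self._incident

    def incident_indices(self, v: str) -> tuple[int, ...]:
        """Indices into ``hyperedges`` of the hyperedges containing v."""
        try:
            return self._incident[v]
        except KeyError:
            raise HypergraphError(f"unknown node {v!r}") from None

    def membership(self, v: str) -> tuple[Hyperedge, ...]:
        """M(v): the hyperedges containing v, in hyperedge order."""
        return tuple(self.hyperedges[j] for j in self.incident_indices(v))

    def flattened(self) -> "Hypergraph":
        """Undirected view: directed hyperedges become tail | head."""
        if not self.directed:
            return self
        flat_edges = [Hyperedge.undirected(e.members, id=e.id) for e in self.hyperedges]
        # Distinct (tail, head) pairs may flatten to the same node set.
        has_dups = len({e.key() for e in flat_edges}) < len(flat_edges)
        return Hypergraph(
            self.nodes, flat_edges, directed=False,
            allow_duplicate_hyperedges=has_dups or self.allow_duplicate_hyperedges,
        )

    def neighbor_sets(self) -> dict[str, set[str]]:
        """For each node v, N(v) = {v} plus all nodes sharing a hyperedge with v."""
        nbrs: dict[str, set[str]] = {v: {v} for v in self.nodes}
        for e in self.hyperedges:
            for v in e.members:
                nbrs[v].update(e.members)
        return nbrs

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.directed == other.directed
            and [(e.id, e.members, e.tail, e.head) for e in self.hyperedges]
            == [(e.id, e.members, e.tail, e.head) for e in other.hyperedges]
        )

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"<Hypergraph {kind}, n={self.n}, m={self.m}>"


class SimpleGraph:
    """Undirected simple graph: no self-loops, no multi-edges.

    Edges are stored as lexicographically sorted node pairs; the node
    tuple keeps insertion order and may contain isolated nodes (graph
    abstractions keep the full metabolite set so that per-node
    frequencies stay comparable across representations).
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise HypergraphError("duplicate node identifiers in node set")
        node_set = set(self.nodes)
        eset: set[tuple[str, str]] = set()
        for u, w in edges:
            if u == w:
                raise HypergraphError(f"self-loop at node {u!r}")
            if u not in node_set or w not in node_set:
                raise HypergraphError(f"edge ({u!r}, {w!r}) has an endpoint outside the node set")
            eset.add((u, w) if u < w else (w, u))
        self.edges: tuple[tuple[str, str], ...] = tuple(sorted(eset))
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, w in self.edges:
            adj[u].add(w)
            adj[w].add(u)
        self._adj = adj

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def l(self) -> int:  # noqa: E741 - the field's symbol for edge count
        return len(self.edges)

    def has_node(self, v: str) -> bool:
        return v in self._adj

    def neighbors(self, v: str) -> set[str]:
        try:
            return set(self._adj[v])
        except KeyError:
            raise HypergraphError(f"unknown node {v!r}") from None

    def degree(self, v: str) -> int:
        try:
            return len(self._adj[v])
        except KeyError:
            raise HypergraphError(f"unknown node {v!r}") from None

    def degrees(self) -> dict[str, int]:
        return {v: len(self._adj[v]) for v in self.nodes}

    def has_edge(self, u: str, w: str) -> bool:
        return w in self._adj.get(u, ())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimpleGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"<SimpleGraph n={self.n}, l={self.l}>"


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary incidence matrix M: rows are nodes, columns hyperedges.

    A binary matrix is a valid incidence matrix iff every row and every
    column contains at least one 1, so isolated nodes are rejected (or
    dropped on request) before construction.
    """

    node_order: tuple[str, ...]
    edge_order: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.node_order), len(self.edge_order)):
            raise HypergraphError("incidence matrix shape does not match row/column labels")
        if not np.isin(m, (0, 1)).all():
            raise HypergraphError("incidence matrix entries must be 0 or 1")
        if m.size and ((m.sum(axis=1) == 0).any() or (m.sum(axis=0) == 0).any()):
            raise HypergraphError("every row and column of an incidence matrix must contain a 1")

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix).sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix).sum(axis=0)


# -- operations ----------------------------------------------------------


def hyper_degree(H: Hypergraph, v: str) -> int:
    """d(v): number of hyperedges containing node v."""
    return len(H.incident_indices(v))


def neighborhood(H: Hypergraph, U: Iterable[str]) -> set[str]:
    """N(U) = union over v in U of N(v); N(v) includes v itself.

    ``U`` may be a single node's singleton or any node subset; the empty
    set maps to the empty set.
    """
    out: set[str] = set()
    for v in U:
        if not H.has_node(v):
            raise HypergraphError(f"unknown node {v!r}")
        out.add(v)
        for j in H.incident_indices(v):
            out.update(H.hyperedges[j].members)
    return out


def incidence_matrix(H: Hypergraph, drop_isolated: bool = False) -> IncidenceMatrix:
    """Binary incidence matrix of H (directed hyperedges flatten to tail | head).

    Isolated nodes would yield an all-zero row, which is not a valid
    incidence matrix; pass ``drop_isolated=True`` to silently drop them
    instead of raising.
    """
    if H.n == 0 or H.m == 0:
        raise HypergraphError("incidence matrix requires at least one node and one hyperedge")
    isolated = [v for v in H.nodes if not H.incident_indices(v)]
    if isolated and not drop_isolated:
        raise HypergraphError(
            f"isolated nodes {isolated} would give all-zero rows; a valid incidence "
            "matrix needs a 1 in every row and column (pass drop_isolated=True to drop them)"
        )
    rows = tuple(v for v in H.nodes if H.incident_indices(v))
    idx = {v: i for i, v in enumerate(rows)}
    mat = np.zeros((len(rows), H.m), dtype=np.int8)
    for j, e in enumerate(H.hyperedges):
        for v in e.members:
            mat[idx[v], j] = 1
    return IncidenceMatrix(rows, tuple(e.id for e in H.hyperedges), mat)


def dual(H: Hypergraph, on_low_degree: str = "drop") -> Hypergraph:
    """Dual hypergraph H': nodes of H' are H's hyperedges; the hyperedge of
    H' contributed by node v is M(v), the set of hyperedges containing v.

    Equivalently the incidence matrix of the dual is the transpose of
    H's.  A node of degree < 2 would contribute a dual hyperedge of
    cardinality < 2; ``on_low_degree`` selects whether such dual
    hyperedges are dropped (default, logged) or raise an error.  A node
    of degree k becomes a dual hyperedge of cardinality k.
    """
    if on_low_degree not in ("drop", "raise"):
        raise ValueError("on_low_degree must be 'drop' or 'raise'")
    flat = H.flattened()
    dual_nodes = tuple(e.id for e in flat.hyperedges)
    dual_edges: list[Hyperedge] = []
    dropped: list[str] = []
    for v in flat.nodes:
        js = flat.incident_indices(v)
        if len(js) < 2:
            if on_low_degree == "raise":
                raise HypergraphError(
                    f"node {v!r} has degree {len(js)} < 2; its dual hyperedge would "
                    "violate the cardinality >= 2 invariant"
                )
            dropped.append(v)
            continue
        dual_edges.append(
            Hyperedge.undirected((flat.hyperedges[j].id for j in js), id=v)
        )
    if dropped:
        logger.info("dual: dropped %d node(s) of degree < 2: %s", len(dropped), dropped)
    # Distinct nodes can sit in exactly the same set of hyperedges, in
    # which case their dual hyperedges coincide as node sets.
    has_dups = len({e.key() for e in dual_edges}) < len(dual_edges)
    return Hypergraph(dual_nodes, dual_edges, directed=False, allow_duplicate_hyperedges=has_dups)


def remove_node(H: Hypergraph, v: str) -> Hypergraph:
    """Delete node v (e.g. a currency metabolite such as water) from H.

    v is removed from the node set and from every hyperedge; hyperedges
    whose cardinality drops below 2 -- or whose tail or head empties, in
    the directed case -- are deleted and logged.
    """
    if not H.has_node(v):
        raise HypergraphError(f"unknown node {v!r}")
    new_nodes = tuple(u for u in H.nodes if u != v)
    kept: list[Hyperedge] = []
    deleted: list[str] = []
    for e in H.hyperedges:
        if v not in e.members:
            kept.append(e)
            continue
        if e.is_directed:
            tail = tuple(u for u in e.tail if u != v)
            head = tuple(u for u in e.head if u != v)
            if not tail or not head:
                deleted.append(e.id)
                continue
            kept.append(Hyperedge.directed(tail, head, id=e.id))
        else:
            members = tuple(u for u in e.members if u != v)
            if len(members) < 2:
                deleted.append(e.id)
                continue
            kept.append(Hyperedge.undirected(members, id=e.id))
    if deleted:
        logger.info("remove_node(%r): deleted hyperedges %s", v, deleted)
    # Removal can make previously distinct hyperedges coincide; keep them
    # only if the input already allowed duplicates, otherwise collapse.
    if not H.allow_duplicate_hyperedges:
        seen: set = set()
        uniq: list[Hyperedge] = []
        for e in kept:
            k = e.key()
            if k in seen:
                logger.info("remove_node(%r): collapsed now-duplicate hyperedge %s", v, e.id)
                continue
            seen.add(k)
            uniq.append(e)
        kept = uniq
    return Hypergraph(
        new_nodes, kept, directed=H.directed,
        allow_duplicate_hyperedges=H.allow_duplicate_hyperedges,
    )


def max_distinct_hyperedges(n: int, k: int) -> int:
    """Maximum number of distinct hyperedges of cardinality k on n nodes: C(n, k)."""
    if not 2 <= k <= n:
        raise HypergraphError(f"cardinality k={k} must satisfy 2 <= k <= n={n}")
    return math.comb(n, k)


def max_nontrivial_hyperedges(n: int) -> int:
    """Maximum number of distinct hyperedges over all cardinalities 2..n-1.

    Excludes the trivial hyperedges (singletons and the full node set):
    sum over k = 2..n-1 of C(n, k) = 2^n - 2n - 2.
    """
    if n < 3:
        raise HypergraphError(f"need n >= 3 nodes for a non-trivial hyperedge, got {n}")
    return sum(math.comb(n, k) for k in range(2, n))
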