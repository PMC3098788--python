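"""Clustering coefficients for standard graphs and hypergraphs.

Standard coefficients
---------------------
``cc_local`` is the Watts-Strogatz local coefficient: the fraction of
realized edges among a node's neighbor pairs.  ``cc_global`` is the
Barrat-Weigt global coefficient: the fraction of 2-paths whose endpoints
are linked (i.e. 3 x triangles / 2-paths).

Hypergraph coefficients
-----------------------
On a hypergraph, two hyperedges through a node already make all their
members mutual neighbors, so naive clique-based clustering is inflated
by construction.  The *extra overlap* of two intersecting hyperedges
Ei, Ej measures instead how well their non-shared members are connected
through the rest of the hypergraph:

    EO(Ei, Ej) = (|Dij ^ N(Dji)| + |Dji ^ N(Dij)|) / (|Dij| + |Dji|)

with Dij = Ei - Ej, Dji = Ej - Ei, and N(.) the hypergraph neighborhood.
EO is 0 for identical or nested pairs and lies in [0, 1].

``hc_local(v)`` averages EO over all pairs of hyperedges containing v;
``hc_global`` averages EO over all intersecting non-identical hyperedge
pairs.  Both lie in [0, 1] and reduce exactly to the Watts-Strogatz and
Barrat-Weigt coefficients of the primal when every hyperedge has
cardinality 2.

``erv_global`` implements the Estrada/Rodriguez-Velazquez coefficient
(hyper-triangles over 2-paths) for comparison; it also reduces to the
standard global coefficient at cardinality 2 but is not bounded by 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .core import Hyperedge, Hypergraph, HypergraphError, SimpleGraph

__all__ = [
    "ClusteringByDegree",
    "cc_local",
    "cc_local_all",
    "cc_global",
    "gamma_min",
    "extra_overlap",
    "hc_local",
    "hc_local_all",
    "hc_global",
    "erv_global",
    "avg_cc_by_degree",
    "clustering_records",
]


# -- standard graph coefficients ------------------------------------------


def cc_local(G: SimpleGraph, v: str) -> float:
    """Watts-Strogatz local clustering coefficient of node v.

    Edges among v's neighbors divided by C(d(v), 2); 0 for degree <= 1,
    where no neighbor pair exists.
    """
    nbrs = sorted(G.neighbors(v))
    d = len(nbrs)
    if d < 2:
        return 0.0
    links = sum(1 for u, w in combinations(nbrs, 2) if G.has_edge(u, w))
    return links / math.comb(d, 2)


def cc_local_all(G: SimpleGraph) -> dict[str, float]:
    """Local clustering coefficient for every node of G."""
    return {v: cc_local(G, v) for v in G.nodes}


def cc_global(G: SimpleGraph) -> float:
    """Barrat-Weigt global clustering coefficient (transitivity).

    Fraction of 2-paths (three distinct nodes joined by two edges) whose
    endpoints are adjacent.  Undefined -- an error, not 0 -- on graphs
    without any 2-path.
    """
    paths = 0
    closed = 0
    for v in G.nodes:
        nbrs = sorted(G.neighbors(v))
        for u, w in combinations(nbrs, 2):
            paths += 1
            if G.has_edge(u, w):
                closed += 1
    if paths == 0:
        raise HypergraphError("global clustering coefficient is undefined: no 2-path in graph")
    return closed / paths


def gamma_min(k: int) -> float:
    """Smallest non-zero local clustering coefficient of a degree-k node.

    A single edge among the k neighbors gives 1 / C(k,2) = 2/(k^2 - k),
    which scales like k^-2 for large k.
    """
    if k < 2:
        raise HypergraphError(f"gamma_min requires degree k >= 2, got {k}")
    return 2.0 / (k * k - k)


# -- extra overlap and the HC coefficients --------------------------------


def _resolve_edge(H: Hypergraph, e) -> Hyperedge:
    if isinstance(e, Hyperedge):
        got = H.edge_by_id(e.id)
        if got is not e and got.key() != e.key():
            raise HypergraphError(f"hyperedge {e.id!r} does not belong to this hypergraph")
        return got
    return H.edge_by_id(e)


def _check_no_duplicates(H: Hypergraph, force: bool) -> None:
    if H.allow_duplicate_hyperedges and not force:
        keys = [e.key() for e in H.hyperedges]
        if len(set(keys)) < len(keys):
            raise HypergraphError(
                "hypergraph contains coinciding hyperedges (e.g. an enzyme/gene union "
                "transform); pass force=True to compute clustering anyway"
            )


def _eo_from_sets(
    ei: frozenset[str], ej: frozenset[str], nbrs: dict[str, set[str]]
) -> float:
    """EO from member sets, given the per-node neighborhood map."""
    dij = ei - ej
    dji = ej - ei
    if not dij or not dji:
        # identical or nested pairs have no extra overlap to measure
        return 0.0
    n_dji: set[str] = set()
    for u in dji:
        n_dji |= nbrs[u]
    n_dij: set[str] = set()
    for u in dij:
        n_dij |= nbrs[u]
    return (len(dij & n_dji) + len(dji & n_dij)) / (len(dij) + len(dji))


def extra_overlap(H: Hypergraph, Ei, Ej, force: bool = False) -> float:
    """EO(Ei, Ej): connectivity of the non-shared members of two hyperedges.

    ``Ei``/``Ej`` may be hyperedge ids or Hyperedge objects of H.
    Neighborhoods are taken over the whole (flattened) hypergraph; the
    differences Dij and Dji are disjoint from the opposite hyperedge by
    construction, so Ei and Ej themselves can never close the overlap.
    """
    _check_no_duplicates(H, force)
    flat = H.flattened()
    ei = _resolve_edge(H, Ei).member_set()
    ej = _resolve_edge(H, Ej).member_set()
    if ei == ej:
        return 0.0
    return _eo_from_sets(ei, ej, flat.neighbor_sets())


def hc_local(H: Hypergraph, v: str, force: bool = False) -> float:
    """Hypergraph local clustering coefficient of node v.

    Mean EO over all unordered pairs of distinct hyperedges containing
    v; 0 when v lies in at most one hyperedge.
    """
    _check_no_duplicates(H, force)
    flat = H.flattened()
    js = flat.incident_indices(v)
    if len(js) < 2:
        return 0.0
    nbrs = flat.neighbor_sets()
    sets = [flat.hyperedges[j].member_set() for j in js]
    total = sum(_eo_from_sets(a, b, nbrs) for a, b in combinations(sets, 2))
    return total / math.comb(len(js), 2)


def hc_local_all(H: Hypergraph, force: bool = False) -> dict[str, float]:
    """hc_local for every node, sharing one neighborhood computation."""
    _check_no_duplicates(H, force)
    flat = H.flattened()
    nbrs = flat.neighbor_sets()
    sets = [e.member_set() for e in flat.hyperedges]
    out: dict[str, float] = {}
    for v in flat.nodes:
        js = flat.incident_indices(v)
        if len(js) < 2:
            out[v] = 0.0
            continue
        total = sum(
            _eo_from_sets(sets[a], sets[b], nbrs)
            for a, b in combinations(js, 2)
        )
        out[v] = total / math.comb(len(js), 2)
    return out


def _intersecting_pairs(flat: Hypergraph) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for v in flat.nodes:
        js = flat.incident_indices(v)
        for a, b in combinations(js, 2):
            pairs.add((a, b))
    return pairs


def hc_global(H: Hypergraph, force: bool = False) -> float:
    """Hypergraph global clustering coefficient.

    Mean EO over I = all unordered pairs of distinct, intersecting
    hyperedges.  Undefined (an error) when no two hyperedges intersect,
    mirroring the standard global coefficient's 2-path precondition.
    """
    _check_no_duplicates(H, force)
    flat = H.flattened()
    sets = [e.member_set() for e in flat.hyperedges]
    pairs = {
        (a, b) for (a, b) in _intersecting_pairs(flat) if sets[a] != sets[b]
    }
    if not pairs:
        raise HypergraphError(
            "hypergraph global clustering is undefined: no two distinct hyperedges intersect"
        )
    nbrs = flat.neighbor_sets()
    total = sum(_eo_from_sets(sets[a], sets[b], nbrs) for a, b in pairs)
    return total / len(pairs)


def erv_global(H: Hypergraph, force: bool = False) -> float:
    """Estrada/Rodriguez-Velazquez hypergraph clustering coefficient.

    6 x (number of hyper-triangles) / (number of 2-path sequences),
    where a hyper-triangle assigns three pairwise-distinct hyperedges to
    the three node pairs of a node triple, and a 2-path is a sequence
    (u, E1, v, E2, w) with u, v, w distinct nodes and E1 != E2 both
    containing v.  The numerator equals the number of closed 3-walks
    that reuse no hyperedge and revisit no node.  Reduces to the
    standard global coefficient at cardinality 2, but is unbounded above
    for larger cardinalities.
    """
    _check_no_duplicates(H, force)
    flat = H.flattened()
    edges = flat.hyperedges
    sets = [e.member_set() for e in edges]

    # ordered 2-path count: center v, ordered pair of distinct incident
    # hyperedges (E1, E2), endpoints u in E1-{v}, w in E2-{v}, u != w
    paths = 0
    for v in flat.nodes:
        js = flat.incident_indices(v)
        for a, b in combinations(js, 2):
            ka, kb = len(sets[a]), len(sets[b])
            shared = len(sets[a] & sets[b]) - 1  # shared besides v
            # unordered contribution; x2 for both orders
            paths += 2 * ((ka - 1) * (kb - 1) - shared)
    if paths == 0:
        raise HypergraphError("ERV coefficient is undefined: no hypergraph 2-path")

    # pair -> hyperedge indices covering it
    pair_edges: dict[tuple[str, str], list[int]] = {}
    for j, s in enumerate(sets):
        for u, w in combinations(sorted(s), 2):
            pair_edges.setdefault((u, w), []).append(j)

    # hyper-triangles: for each node triple with all three pairs covered,
    # count assignments of pairwise-distinct hyperedges to the pairs
    adj: dict[str, set[str]] = {}
    for (u, w) in pair_edges:
        adj.setdefault(u, set()).add(w)
        adj.setdefault(w, set()).add(u)
    triangles = 0
    for (u, w), cover_uw in pair_edges.items():
        # third node x > w keeps each triple counted once (u < w < x)
        for x in sorted(adj[u] & adj[w]):
            if x <= w:
                continue
            a = len(pair_edges[(u, w)])
            b = len(pair_edges[(w, x)])
            c = len(pair_edges[(u, x)])
            t = len(set(pair_edges[(u, w)]) & set(pair_edges[(w, x)]) & set(pair_edges[(u, x)]))
            triangles += a * b * c - t * (a + b + c) + 2 * t
    return 6.0 * triangles / paths


# -- degree-binned averages ------------------------------------------------


@dataclass(frozen=True)
class ClusteringByDegree:
    """Average clustering coefficient per degree: the C(k) curve."""

    degrees: tuple[int, ...]
    mean_coefficient: tuple[float, ...]
    count: tuple[int, ...]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.degrees, self.mean_coefficient))


def clustering_records(G: SimpleGraph) -> list[tuple[str, int, float]]:
    """Per-node (node, degree, local coefficient) records for a graph."""
    return [(v, G.degree(v), cc_local(G, v)) for v in G.nodes]


def avg_cc_by_degree(
    records: Iterable[tuple], exclude_zero: bool = False
) -> ClusteringByDegree:
    """Group per-node (degree, coefficient) records and average per degree.

    Records may be (degree, coefficient) pairs or (node, degree,
    coefficient) triples.  With ``exclude_zero`` nodes whose coefficient
    is 0 are dropped before averaging, and degrees left without any node
    are omitted -- the variant used to compare sparse random graphs with
    the minimal-clustering curve.
    """
    rows: list[tuple[int, float]] = []
    for rec in records:
        if len(rec) == 3:
            _, k, c = rec
        else:
            k, c = rec
        rows.append((int(k), float(c)))
    if not rows:
        raise HypergraphError("avg_cc_by_degree requires at least one record")
    if exclude_zero:
        rows = [(k, c) for k, c in rows if c != 0.0]
    grouped: dict[int, list[float]] = {}
    for k, c in rows:
        grouped.setdefault(k, []).append(c)
    degrees = tuple(sorted(grouped))
    means = tuple(float(np.mean(grouped[k])) for k in degrees)
    counts = tuple(len(grouped[k]) for k in degrees)
    return ClusteringByDegree(degrees, means, counts)
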