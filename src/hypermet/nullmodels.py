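"""Seedable random generators and rewiring null models.

Null models for metabolic networks should preserve the features one is
*not* testing.  Three rewiring procedures are provided:

* ``rewire_graph_simple`` -- remove a uniform edge, link a uniform
  currently-unconnected node pair; preserves (n, l).
* ``rewire_graph_degree_preserving`` -- double-edge swaps on disjoint
  edge pairs; preserves the entire degree sequence.
* ``rewire_hypergraph`` -- remove a uniform hyperedge and resample a
  fresh node set of the same cardinality (same tail/head sizes in the
  directed case); preserves the number and cardinality distribution of
  hyperedges, the key quantity standard-graph null models ignore.

Generators produce fixed-cardinality random hypergraphs, Erdos-Renyi
graphs with an exact edge count, and "metabolic-like" hypergraphs whose
cardinalities follow a shifted binomial law (mean ~ 4.2, support 2-10),
matching the empirically observed reaction-size distribution.

Every operation takes either an integer seed or a ``numpy`` Generator;
no global random state is touched, so replica ensembles can be seeded
independently and reproduced bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Hyperedge, Hypergraph, HypergraphError, SimpleGraph, max_distinct_hyperedges

__all__ = [
    "RewireConfig",
    "gen_fixed_cardinality",
    "gen_erdos_renyi",
    "gen_binomial_hypergraph",
    "rewire_hypergraph",
    "rewire_graph_simple",
    "rewire_graph_degree_preserving",
]


@dataclass(frozen=True)
class RewireConfig:
    """Configuration of a rewiring run.

    ``n_operations`` counts *successful* operations: an attempt rejected
    because it would duplicate an existing edge/hyperedge is retried (up
    to ``max_retries_per_op``) and does not consume an operation, so the
    stated operation count keeps its meaning on sparse networks.
    """

    n_operations: int
    seed: int | None = None
    max_retries_per_op: int = 100

    def __post_init__(self):
        if self.n_operations < 0:
            raise ValueError("n_operations must be >= 0")
        if self.max_retries_per_op < 1:
            raise ValueError("max_retries_per_op must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _node_labels(n: int) -> tuple[str, ...]:
    width = len(str(n - 1)) if n > 1 else 1
    return tuple(f"v{i:0{width}d}" for i in range(n))


def gen_fixed_cardinality(
    n: int,
    m: int | None,
    k: int,
    seed=None,
    stop_at_primal_edges: int | None = None,
) -> Hypergraph:
    """Random undirected hypergraph: m distinct hyperedges, all of cardinality k.

    Each hyperedge is a uniform k-subset of the n nodes, resampled on
    collision with an already-drawn hyperedge so all hyperedges are
    distinct.  Alternatively ``stop_at_primal_edges`` keeps adding
    hyperedges until the primal of the hypergraph has at least that many
    edges (in which case ``m`` may be None or acts as a hard cap).
    """
    rng = _rng(seed)
    if not 2 <= k <= n:
        raise HypergraphError(f"cardinality k={k} must satisfy 2 <= k <= n={n}")
    max_m = max_distinct_hyperedges(n, k)
    if stop_at_primal_edges is None:
        if m is None:
            raise ValueError("either m or stop_at_primal_edges must be given")
        if m > max_m:
            raise HypergraphError(f"m={m} exceeds the C({n},{k})={max_m} distinct k-subsets")
    cap = m if m is not None else max_m
    nodes = _node_labels(n)
    seen: set[frozenset[str]] = set()
    edges: list[Hyperedge] = []
    primal_pairs: set[tuple[str, str]] = set()
    # generous global retry budget: collisions are rare in sparse regimes
    retries = 0
    max_retries = 1000 * max(cap, 1) + 1000
    while len(edges) < cap:
        members = tuple(sorted(nodes[i] for i in rng.choice(n, size=k, replace=False)))
        key = frozenset(members)
        if key in seen:
            retries += 1
            if retries > max_retries:
                raise HypergraphError(
                    f"retry budget exhausted after {len(edges)} hyperedges; "
                    "the requested hypergraph is too dense"
                )
            continue
        seen.add(key)
        edges.append(Hyperedge.undirected(members))
        if stop_at_primal_edges is not None:
            for i in range(k):
                for j in range(i + 1, k):
                    primal_pairs.add((members[i], members[j]))
            if len(primal_pairs) >= stop_at_primal_edges:
                break
    return Hypergraph(nodes, edges, directed=False)


def gen_erdos_renyi(n: int, l: int, seed=None) -> SimpleGraph:  # noqa: E741
    """Uniform simple graph with exactly l edges on n nodes (G(n, l) model)."""
    import networkx as nx

    rng = _rng(seed)
    total = math.comb(n, 2)
    if l > total:
        raise HypergraphError(f"l={l} exceeds C({n},2)={total}")
    nodes = _node_labels(n)
    g = nx.gnm_random_graph(n, l, seed=rng)
    return SimpleGraph(nodes, ((nodes[u], nodes[w]) for u, w in g.edges()))


def gen_binomial_hypergraph(
    n: int,
    m: int,
    mean_cardinality: float = 4.19,
    n_trials: int = 8,
    directed: bool = False,
    seed=None,
) -> Hypergraph:
    """Random hypergraph emulating a metabolic reaction-size distribution.

    Hyperedge cardinalities are drawn as 2 + Binomial(n_trials, q) with q
    chosen so the expected cardinality equals ``mean_cardinality``; the
    defaults (mean 4.19, support 2..10) reproduce the shape observed for
    real metabolic networks.  Node sets are uniform without replacement
    and pairwise distinct.  In directed mode each sampled set is split
    uniformly at random into a non-empty tail and head.
    """
    rng = _rng(seed)
    if mean_cardinality < 2:
        raise HypergraphError("mean_cardinality must be >= 2")
    if n_trials < 1:
        raise HypergraphError("n_trials must be >= 1")
    q = (mean_cardinality - 2.0) / n_trials
    if not 0.0 <= q <= 1.0:
        raise HypergraphError(
            f"infeasible parameters: mean {mean_cardinality} needs success probability "
            f"{q:.3f} outside [0, 1] with {n_trials} trials"
        )
    if 2 + n_trials > n:
        raise HypergraphError(f"maximum cardinality {2 + n_trials} exceeds n={n}")
    nodes = _node_labels(n)
    seen: set = set()
    edges: list[Hyperedge] = []
    retries = 0
    max_retries = 1000 * m + 1000
    while len(edges) < m:
        k = 2 + int(rng.binomial(n_trials, q))
        members = tuple(sorted(nodes[i] for i in rng.choice(n, size=k, replace=False)))
        if directed:
            # uniform proper bipartition via rejection on empty sides
            while True:
                mask = rng.integers(0, 2, size=k)
                if 0 < mask.sum() < k:
                    break
            tail = tuple(v for v, b in zip(members, mask) if b)
            head = tuple(v for v, b in zip(members, mask) if not b)
            edge = Hyperedge.directed(tail, head)
        else:
            edge = Hyperedge.undirected(members)
        if edge.key() in seen:
            retries += 1
            if retries > max_retries:
                raise HypergraphError("retry budget exhausted; parameters too dense")
            continue
        seen.add(edge.key())
        edges.append(edge)
    return Hypergraph(nodes, edges, directed=directed)


def rewire_hypergraph(H: Hypergraph, cfg: RewireConfig) -> Hypergraph:
    """Cardinality-preserving hypergraph rewiring.

    Each operation removes a uniformly chosen hyperedge and replaces it
    with a fresh uniform node set of the same cardinality (same tail and
    head sizes for a directed hypergraph), rejecting replacements that
    would duplicate an existing hyperedge.  The node set, hyperedge
    count and cardinality multiset are preserved exactly; overlaps
    between hyperedges are not.
    """
    rng = cfg.rng()
    nodes = H.nodes
    n = len(nodes)
    edges: list[Hyperedge] = list(H.hyperedges)
    keys: set = {e.key() for e in edges}
    if len(keys) != len(edges):
        raise HypergraphError("cannot rewire a hypergraph with duplicate hyperedges")
    for _ in range(cfg.n_operations):
        victim_idx = int(rng.integers(len(edges)))
        victim = edges[victim_idx]
        keys.discard(victim.key())
        for attempt in range(cfg.max_retries_per_op):
            if victim.is_directed:
                t_size, h_size = len(victim.tail), len(victim.head)
                draw = rng.choice(n, size=t_size + h_size, replace=False)
                new = Hyperedge.directed(
                    (nodes[i] for i in draw[:t_size]),
                    (nodes[i] for i in draw[t_size:]),
                    id=victim.id,
                )
            else:
                draw = rng.choice(n, size=victim.cardinality, replace=False)
                new = Hyperedge.undirected((nodes[i] for i in draw), id=victim.id)
            if new.key() not in keys:
                break
        else:
            keys.add(victim.key())
            raise HypergraphError(
                f"retry budget ({cfg.max_retries_per_op}) exhausted while rewiring; "
                "the hypergraph is too dense"
            )
        keys.add(new.key())
        edges[victim_idx] = new
    return Hypergraph(nodes, edges, directed=H.directed)


def rewire_graph_simple(G: SimpleGraph, cfg: RewireConfig) -> SimpleGraph:
    """Edge-count-preserving rewiring of a simple graph.

    Each operation removes a uniformly chosen edge and links a uniformly
    chosen pair of currently unconnected nodes.  Degrees are not
    preserved; repeated application drives the graph toward the
    Erdos-Renyi ensemble with the same (n, l).
    """
    if cfg.n_operations > 0:
        if G.l < 1:
            raise HypergraphError("rewiring requires at least one edge")
        if G.l >= math.comb(G.n, 2):
            raise HypergraphError("complete graph: no unconnected pair to link")
    rng = cfg.rng()
    nodes = G.nodes
    n = len(nodes)
    edges: list[tuple[str, str]] = list(G.edges)
    eset: set[tuple[str, str]] = set(edges)
    for _ in range(cfg.n_operations):
        victim_idx = int(rng.integers(len(edges)))
        victim = edges[victim_idx]
        eset.discard(victim)
        for attempt in range(cfg.max_retries_per_op):
            i, j = rng.choice(n, size=2, replace=False)
            u, w = nodes[int(i)], nodes[int(j)]
            pair = (u, w) if u < w else (w, u)
            if pair not in eset:
                break
        else:
            eset.add(victim)
            raise HypergraphError(
                f"retry budget ({cfg.max_retries_per_op}) exhausted; graph too dense"
            )
        eset.add(pair)
        edges[victim_idx] = pair
    return SimpleGraph(nodes, edges)


def rewire_graph_degree_preserving(G: SimpleGraph, cfg: RewireConfig) -> SimpleGraph:
    """Degree-preserving rewiring by double-edge swaps.

    Each operation picks two edges sharing no endpoint, {a,b} and {c,d},
    and swaps endpoints to {a,d},{c,b} or {a,c},{b,d} (uniform choice),
    rejecting swaps that would duplicate an existing edge.  Every node's
    degree is preserved exactly.
    """
    if cfg.n_operations > 0 and G.l < 2:
        raise HypergraphError("degree-preserving rewiring requires at least two edges")
    rng = cfg.rng()
    edges: list[tuple[str, str]] = list(G.edges)
    eset: set[tuple[str, str]] = set(edges)

    def norm(u: str, w: str) -> tuple[str, str]:
        return (u, w) if u < w else (w, u)

    for _ in range(cfg.n_operations):
        for attempt in range(cfg.max_retries_per_op):
            i1, i2 = rng.choice(len(edges), size=2, replace=False)
            a, b = edges[int(i1)]
            c, d = edges[int(i2)]
            if len({a, b, c, d}) < 4:
                continue  # edges share an endpoint
            if rng.integers(2):
                e1, e2 = norm(a, d), norm(c, b)
            else:
                e1, e2 = norm(a, c), norm(b, d)
            if e1 in eset or e2 in eset:
                continue
            eset.discard(edges[int(i1)])
            eset.discard(edges[int(i2)])
            eset.add(e1)
            eset.add(e2)
            edges[int(i1)] = e1
            edges[int(i2)] = e2
            break
        else:
            raise HypergraphError(
                f"no valid degree-preserving swap within {cfg.max_retries_per_op} attempts"
            )
    return SimpleGraph(G.nodes, edges)
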