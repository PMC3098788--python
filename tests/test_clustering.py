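"""Clustering coefficients: standard, extra-overlap based, and ERV.

Brute-force oracles here recompute every quantity from first principles
(explicit loops over hyperedges, node triples and walk sequences) and
are kept independent of the library's internals.
"""

import math
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from hypermet import (
    Hyperedge,
    Hypergraph,
    HypergraphError,
    SimpleGraph,
    avg_cc_by_degree,
    cc_global,
    cc_local,
    erv_global,
    extra_overlap,
    gamma_min,
    hc_global,
    hc_local,
    hc_local_all,
    primal,
    union_transform,
)
from conftest import random_hypergraph


# -- independent oracles ---------------------------------------------------


def neighborhood_brute(H, nodes):
    """N(U) by scanning all hyperedges for each node."""
    out = set()
    for v in nodes:
        out.add(v)
        for e in H.hyperedges:
            if v in e.members:
                out.update(e.members)
    return out


def eo_brute(H, ei, ej):
    a, b = set(ei.members), set(ej.members)
    if a == b:
        return 0.0
    dij, dji = a - b, b - a
    if not dij or not dji:
        return 0.0
    num = len(dij & neighborhood_brute(H, dji)) + len(dji & neighborhood_brute(H, dij))
    return num / (len(dij) + len(dji))


def hc_local_brute(H, v):
    incident = [e for e in H.hyperedges if v in e.members]
    if len(incident) < 2:
        return 0.0
    pairs = list(combinations(incident, 2))
    return sum(eo_brute(H, a, b) for a, b in pairs) / len(pairs)


def hc_global_brute(H):
    pairs = [
        (a, b)
        for a, b in combinations(H.hyperedges, 2)
        if set(a.members) & set(b.members) and set(a.members) != set(b.members)
    ]
    if not pairs:
        raise ValueError("undefined")
    return sum(eo_brute(H, a, b) for a, b in pairs) / len(pairs)


def erv_brute(H):
    """Closed 3-walks over ordered node/hyperedge sequences, divided by
    ordered 2-path sequences."""
    edges = H.hyperedges
    nodes = H.nodes
    paths = 0
    for u, v, w in permutations(nodes, 3):
        for e1 in edges:
            for e2 in edges:
                if e1 is e2:
                    continue
                if {u, v} <= set(e1.members) and {v, w} <= set(e2.members):
                    paths += 1
    # each unordered 2-path {u, E1, v, E2, w} appears twice above (both
    # traversal orders); `paths` is the ordered-sequence count
    walks = 0
    for u, v, w in permutations(nodes, 3):
        for e1, e2, e3 in permutations(edges, 3):
            if (
                {u, v} <= set(e1.members)
                and {v, w} <= set(e2.members)
                and {w, u} <= set(e3.members)
            ):
                walks += 1
    if paths == 0:
        raise ValueError("undefined")
    # walks counts each hyper-triangle 6 times (3 starts x 2 directions)
    return walks / paths


# -- standard coefficients -------------------------------------------------


class TestStandardClustering:
    def test_triangle_and_open_path(self):
        tri = SimpleGraph("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        path = SimpleGraph("ABC", [("A", "B"), ("B", "C")])
        assert cc_local(tri, "A") == 1.0
        assert cc_local(path, "B") == 0.0

    def test_single_neighbor_edge_value(self):
        # k neighbors with exactly one edge among them: C = 2/(k^2 - k)
        g = SimpleGraph(
            "vabcd", [("v", "a"), ("v", "b"), ("v", "c"), ("v", "d"), ("a", "b")]
        )
        assert cc_local(g, "v") == pytest.approx(2 / (16 - 4))

    def test_against_networkx(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            h = random_hypergraph(rng)
            g = primal(h)
            gx = g.to_networkx()
            for v in g.nodes:
                assert cc_local(g, v) == pytest.approx(nx.clustering(gx, v), abs=1e-12)

    def test_global_complete_and_star(self):
        k4 = SimpleGraph("ABCD", [(u, w) for u, w in combinations("ABCD", 2)])
        assert cc_global(k4) == 1.0
        star = SimpleGraph("cabd", [("c", "a"), ("c", "b"), ("c", "d")])
        assert cc_global(star) == 0.0

    def test_global_triangle_plus_pendant(self):
        g = SimpleGraph("ABCD", [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert cc_global(g) == pytest.approx(3 / 5)
        assert cc_global(g) == pytest.approx(nx.transitivity(g.to_networkx()), abs=1e-12)

    def test_global_undefined_without_two_path(self):
        g = SimpleGraph("ABCD", [("A", "B"), ("C", "D")])
        with pytest.raises(HypergraphError):
            cc_global(g)

    def test_gamma_min_values_and_domain(self):
        assert gamma_min(2) == 1.0
        assert gamma_min(3) == pytest.approx(1 / 3)
        with pytest.raises(HypergraphError):
            gamma_min(1)


# -- extra overlap ---------------------------------------------------------


class TestExtraOverlap:
    def test_third_edge_closure(self):
        h = Hypergraph(
            "vab",
            [
                Hyperedge.undirected(["v", "a"], id="E1"),
                Hyperedge.undirected(["v", "b"], id="E2"),
                Hyperedge.undirected(["a", "b"], id="E3"),
            ],
        )
        assert extra_overlap(h, "E1", "E2") == 1.0

    def test_nested_pair_is_zero(self):
        h = Hypergraph(
            "abc",
            [
                Hyperedge.undirected(["a", "b", "c"], id="E"),
                Hyperedge.undirected(["a", "b"], id="Ep"),
            ],
        )
        assert extra_overlap(h, "E", "Ep") == 0.0

    def test_mixed_cardinality_example(self):
        h = Hypergraph(
            "vabc",
            [
                Hyperedge.undirected(["v", "a", "b"], id="E1"),
                Hyperedge.undirected(["v", "c"], id="E2"),
                Hyperedge.undirected(["b", "c"], id="E3"),
            ],
        )
        assert extra_overlap(h, "E1", "E2") == pytest.approx(2 / 3)

    def test_unknown_hyperedge_errors(self):
        h = Hypergraph("ab", [Hyperedge.undirected(["a", "b"], id="E1")])
        with pytest.raises(HypergraphError):
            extra_overlap(h, "E1", "E9")

    def test_own_edges_cannot_close_overlap(self):
        # recompute EO with the pair deleted from the neighborhood
        # computation; by construction the result cannot change
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(40):
            h = random_hypergraph(rng)
            for a, b in combinations(h.hyperedges, 2):
                rest = [e for e in h.hyperedges if e is not a and e is not b]
                h_rest = Hypergraph(h.nodes, rest, allow_duplicate_hyperedges=True)
                assert extra_overlap(h, a.id, b.id) == pytest.approx(
                    eo_brute(h_rest, a, b), abs=1e-15
                )
                checked += 1
        assert checked > 50


# -- hypergraph clustering coefficients ------------------------------------


class TestHCCoefficients:
    def test_single_membership_is_zero(self):
        h = Hypergraph("abc", [Hyperedge.undirected(["a", "b", "c"])])
        assert hc_local(h, "a") == 0.0

    def test_reduction_to_standard_on_cardinality_two(self):
        # P2: on standard graphs the HC measures equal the classical ones
        rng = np.random.default_rng(2)
        for _ in range(15):
            h = random_hypergraph(rng, max_nodes=10, max_edges=8, max_card=2)
            g = primal(h)
            gx = g.to_networkx()
            for v in h.nodes:
                assert hc_local(h, v) == pytest.approx(nx.clustering(gx, v), abs=1e-12)
            try:
                hg = hc_global(h)
            except HypergraphError:
                continue
            assert hg == pytest.approx(nx.transitivity(gx), abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            h = random_hypergraph(rng)
            for v in h.nodes:
                assert 0.0 <= hc_local(h, v) <= 1.0
            try:
                assert 0.0 <= hc_global(h) <= 1.0
            except HypergraphError:
                pass

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            h = random_hypergraph(rng)
            coeffs = hc_local_all(h)
            for v in h.nodes:
                assert coeffs[v] == pytest.approx(hc_local_brute(h, v), abs=1e-12)
            try:
                expected = hc_global_brute(h)
            except ValueError:
                with pytest.raises(HypergraphError):
                    hc_global(h)
                continue
            assert hc_global(h) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_hyperedges_undefined(self):
        h = Hypergraph("abcd", [Hyperedge.undirected("ab"), Hyperedge.undirected("cd")])
        with pytest.raises(HypergraphError):
            hc_global(h)

    def test_complete_pair_hypergraph_is_one(self):
        nodes = list("abcd")
        h = Hypergraph(nodes, [Hyperedge.undirected(p) for p in combinations(nodes, 2)])
        assert hc_global(h) == pytest.approx(1.0)

    def test_duplicate_flagged_input_refused_without_force(self):
        h = Hypergraph("abc", [Hyperedge.undirected("ab"), Hyperedge.undirected("bc")])
        u = union_transform(h, [["E1", "E2"], ["E1", "E2"], ["E1"]])
        with pytest.raises(HypergraphError):
            hc_global(u)
        # coincident pairs are skipped; the nested pairs have EO 0
        assert hc_global(u, force=True) == 0.0


class TestERV:
    def test_reduction_to_transitivity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            h = random_hypergraph(rng, max_nodes=10, max_edges=8, max_card=2)
            g = primal(h).to_networkx()
            try:
                val = erv_global(h)
            except HypergraphError:
                continue
            assert val == pytest.approx(nx.transitivity(g), abs=1e-12)

    def test_exceeds_one_on_dense_cardinality_three(self):
        nodes = list("abcde")
        h = Hypergraph(nodes, [Hyperedge.undirected(c) for c in combinations(nodes, 3)])
        assert erv_global(h) > 1.0

    def test_matches_walk_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            h = random_hypergraph(rng, max_nodes=7, max_edges=4)
            try:
                expected = erv_brute(h)
            except ValueError:
                with pytest.raises(HypergraphError):
                    erv_global(h)
                continue
            assert erv_global(h) == pytest.approx(expected, abs=1e-12)

    def test_no_two_path_is_undefined(self):
        h = Hypergraph("abcd", [Hyperedge.undirected("ab"), Hyperedge.undirected("cd")])
        with pytest.raises(HypergraphError):
            erv_global(h)


class TestAvgByDegree:
    def test_mean_and_exclude_zero(self):
        recs = [(4, 0.0), (4, 1.0), (4, 0.0), (4, 1.0)]
        assert avg_cc_by_degree(recs).as_dict() == {4: 0.5}
        assert avg_cc_by_degree(recs, exclude_zero=True).as_dict() == {4: 1.0}

    def test_counts_partition_nodes(self):
        rng = np.random.default_rng(7)
        h = random_hypergraph(rng, max_nodes=8)
        g = primal(h)
        recs = [(g.degree(v), cc_local(g, v)) for v in g.nodes]
        table = avg_cc_by_degree(recs)
        assert sum(table.count) == g.n

    def test_triple_records_accepted(self):
        table = avg_cc_by_degree([("x", 3, 0.5), ("y", 3, 0.1)])
        assert table.as_dict()[3] == pytest.approx(0.3)
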