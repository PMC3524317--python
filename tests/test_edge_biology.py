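from __future__ import annotations

from itertools import chain, combinations

import networkx as nx
import pytest

from cliquesig.edge_biology import edge_strength, go_distance, pathway_similarity
from cliquesig.io_formats import AnnotationMap
from tests.conftest import net_from_edges


class TestGoDistance:
    def test_identical_sets_zero(self):
        assert go_distance({"t1", "t2"}, {"t1", "t2"}) == 0.0

    def test_disjoint_sets_one(self):
        assert go_distance({"t1"}, {"t2"}) == 1.0

    def test_partial_overlap(self):
        # |sym diff| = 2, |union| = 3, |intersection| = 1 -> 2/4
        assert go_distance({"t1", "t2"}, {"t2", "t3"}) == pytest.approx(0.5)

    def test_empty_set_undefined(self):
        with pytest.raises(ValueError):
            go_distance(set(), {"t1"})

    def test_symmetric_bounded_and_shared_term_monotone(self):
        """Adding a shared term to both sets never increases the distance;
        checked exhaustively over all subset pairs of a 5-term universe."""
        universe = ["a", "b", "c", "d", "e"]
        subsets = [
            set(s)
            for s in chain.from_iterable(
                combinations(universe, r) for r in range(1, 6)
            )
        ]
        for A in subsets:
            for B in subsets:
                d = go_distance(A, B)
                assert 0.0 <= d <= 1.0
                assert d == pytest.approx(go_distance(B, A))
                extra = next((t for t in universe if t not in A | B), None)
                if extra is not None:
                    assert go_distance(A | {extra}, B | {extra}) <= d + 1e-12


class TestPathwaySimilarity:
    def test_disjoint_zero(self):
        assert pathway_similarity({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        # (1/2 + 1/2) / |{a,b,c}| = 1/3
        assert pathway_similarity({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_identical_singletons_exceed_one(self):
        # the raw score is unbounded above 1; normalization absorbs the scale
        assert pathway_similarity({"a"}, {"a"}) == pytest.approx(2.0)

    def test_empty_set_zero(self):
        assert pathway_similarity(set(), {"a"}) == 0.0

    def test_symmetric(self):
        assert pathway_similarity({"a", "b"}, {"b"}) == pytest.approx(
            pathway_similarity({"b"}, {"a", "b"})
        )


def _annot(mapping):
    return AnnotationMap(
        gene_to_terms={g: frozenset(t) for g, t in mapping.items()}
    )


class TestEdgeStrength:
    def test_single_edge_constant_convention(self):
        net = net_from_edges([("a", "b")])
        net.graph.edges["a", "b"]["pcc"] = 0.9
        go = _annot({"a": {"t1"}, "b": {"t1"}})
        pw = _annot({"a": {"p1"}, "b": {"p1"}})
        scores = edge_strength(net, go, pw)
        assert scores[("a", "b")]["edge_strength"] == pytest.approx(1.0)

    def test_max_of_all_features_scores_one(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        net.graph.edges["a", "b"]["pcc"] = 0.95
        net.graph.edges["b", "c"]["pcc"] = 0.7
        net.graph.edges["a", "c"]["pcc"] = -0.65
        go = _annot({"a": {"t1", "t2"}, "b": {"t1", "t2"}, "c": {"t9"}})
        pw = _annot({"a": {"p1"}, "b": {"p1"}, "c": {"p2"}})
        scores = edge_strength(net, go, pw)
        assert scores[("a", "b")]["edge_strength"] == pytest.approx(1.0)
        for e in [("a", "c"), ("b", "c")]:
            assert scores[e]["edge_strength"] < 1.0

    def test_hand_computed_three_edge_fixture(self):
        """Averages of the min-max normalized triplet match a spreadsheet-style
        hand computation."""
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        net.graph.edges["a", "b"]["pcc"] = 0.9
        net.graph.edges["b", "c"]["pcc"] = 0.7
        net.graph.edges["a", "c"]["pcc"] = 0.8
        go = _annot(
            {"a": {"t1", "t2"}, "b": {"t1", "t2"}, "c": {"t3"}}
        )  # d(ab)=0, d(bc)=1, d(ac)=1
        pw = _annot(
            {"a": {"p1", "p2"}, "b": {"p2", "p3"}, "c": {"p1", "p2"}}
        )  # s(ab)=1/3, s(bc)=1/3, s(ac)=(2/2+2/2)/2=1
        # raw features (|pcc|, go sim = 1-d, pathway):
        #   ab: (0.9, 1, 1/3)   bc: (0.7, 0, 1/3)   ac: (0.8, 0, 1.0)
        # min-max per feature:
        #   pcc: ab=1, bc=0, ac=0.5 ; go: ab=1, bc=0, ac=0
        #   pw:  ab=0, bc=0, ac=1
        expected = {
            ("a", "b"): (1 + 1 + 0) / 3,
            ("b", "c"): (0 + 0 + 0) / 3,
            ("a", "c"): (0.5 + 0 + 1) / 3,
        }
        scores = edge_strength(net, go, pw)
        for e, want in expected.items():
            assert scores[e]["edge_strength"] == pytest.approx(want)

    def test_unannotated_gene_gets_median_and_flag(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        for e, r in [(("a", "b"), 0.9), (("b", "c"), 0.7), (("a", "c"), 0.8)]:
            net.graph.edges[e]["pcc"] = r
        go = _annot({"a": {"t1"}, "b": {"t1"}})  # c unannotated
        pw = _annot({"a": {"p1"}, "b": {"p1"}, "c": {"p1"}})
        scores = edge_strength(net, go, pw)
        assert scores[("b", "c")]["go_unannotated"]
        # both c-edges got the median (= the only observed value, 0.0)
        assert scores[("b", "c")]["go_distance"] == pytest.approx(0.0)
        assert not scores[("a", "b")]["go_unannotated"]

    def test_go_interacting_flag(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        net.graph.edges["a", "b"]["pcc"] = 0.9
        net.graph.edges["b", "c"]["pcc"] = 0.8
        go = _annot({"a": {"t1", "t2"}, "b": {"t2"}, "c": {"t9"}})
        pw = _annot({"a": {"p1"}, "b": {"p1"}, "c": {"p1"}})
        scores = edge_strength(net, go, pw)
        assert scores[("a", "b")]["go_interacting"]  # distance 1/3 < 1
        assert not scores[("b", "c")]["go_interacting"]  # disjoint, distance 1

    def test_invariant_under_edge_insertion_order(self):
        go = _annot({"a": {"t1"}, "b": {"t1", "t2"}, "c": {"t2"}})
        pw = _annot({"a": {"p1"}, "b": {"p2"}, "c": {"p1", "p2"}})
        edges = [("a", "b"), ("b", "c"), ("a", "c")]
        pccs = {("a", "b"): 0.9, ("b", "c"): 0.7, ("a", "c"): -0.8}
        nets = []
        for order in (edges, list(reversed(edges))):
            net = net_from_edges(order)
            for e, r in pccs.items():
                net.graph.edges[e]["pcc"] = r
            nets.append(edge_strength(net, go, pw))
        assert nets[0] == nets[1]

    def test_direction_flag_reverses_go_feature(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        for e, r in [(("a", "b"), 0.8), (("b", "c"), 0.8), (("a", "c"), 0.8)]:
            net.graph.edges[e]["pcc"] = r
        go = _annot({"a": {"t1"}, "b": {"t1"}, "c": {"t9"}})
        pw = _annot({"a": {"p1"}, "b": {"p1"}, "c": {"p1"}})
        as_sim = edge_strength(net, go, pw, go_as_similarity=True)
        as_dist = edge_strength(
            net_from_copy(net, [0.8, 0.8, 0.8]), go, pw, go_as_similarity=False
        )
        assert as_sim[("a", "b")]["go_norm"] == pytest.approx(
            1.0 - as_dist[("a", "b")]["go_norm"]
        )


def net_from_copy(net, pccs):
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for (a, b), r in zip(sorted(tuple(sorted(e)) for e in net.graph.edges), pccs):
        g.add_edge(a, b, pcc=r)
    from cliquesig.network_build import AnnotatedNetwork

    return AnnotatedNetwork(graph=g)
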