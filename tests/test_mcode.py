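"""Molecular complex detection vs an independently coded naive reference."""

import itertools

import networkx as nx
import pytest

from obesinet.core import ValidationError
from obesinet.mcode import (
    Cluster,
    McodeParams,
    core_decomposition,
    expand_first_neighbors,
    filter_clusters,
    predict_complexes,
    vertex_weight,
)
from obesinet.network import EdgeRecord, Network, build_network
from reference_mcode import ref_core_numbers, ref_predict, ref_vertex_weight


def _net(pairs, nodes=()):
    net = build_network([EdgeRecord(a, b, 0.9) for a, b in pairs], "Experimental")
    net.graph.add_nodes_from(nodes)
    return net


def _k(n, prefix="K"):
    names = [f"{prefix}{i}" for i in range(n)]
    return list(itertools.combinations(names, 2)), names


class TestCoreDecomposition:
    def test_complete_graph(self):
        pairs, names = _k(5)
        cores = core_decomposition(_net(pairs))
        assert all(cores[v] == 4 for v in names)

    def test_tree_cores_at_most_one(self):
        tree = nx.random_labeled_tree(12, seed=4)
        cores = core_decomposition(_net([(f"T{a}", f"T{b}") for a, b in tree.edges]))
        assert max(cores.values()) <= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_peeling(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        pairs = [(f"G{a}", f"G{b}") for a, b in g.edges]
        net = _net(pairs, nodes=[f"G{i}" for i in range(12)])
        assert core_decomposition(net) == ref_core_numbers(net.nodes(), pairs)

    def test_monotone_under_edge_addition(self):
        g = nx.gnp_random_graph(10, 0.25, seed=2)
        pairs = [(f"G{a}", f"G{b}") for a, b in g.edges]
        before = core_decomposition(_net(pairs, nodes=[f"G{i}" for i in range(10)]))
        extra = [("G0", "G9"), ("G1", "G8"), ("G2", "G7")]
        after = core_decomposition(
            _net(pairs + extra, nodes=[f"G{i}" for i in range(10)])
        )
        assert all(after[v] >= before[v] for v in before)


class TestVertexWeight:
    def test_clique_member(self):
        pairs, names = _k(5)
        assert vertex_weight(_net(pairs), names[0]) == pytest.approx(4.0)

    def test_star_center(self):
        pairs = [("HUB", f"L{i}") for i in range(4)]
        assert vertex_weight(_net(pairs), "HUB") == pytest.approx(0.4)

    def test_isolated_vertex(self):
        net = _net([("A", "B")], nodes=["LONER"])
        assert vertex_weight(net, "LONER") == 0.0

    def test_unknown_vertex_rejected(self):
        with pytest.raises(ValidationError):
            vertex_weight(_net([("A", "B")]), "NOPE")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_reference(self, seed):
        g = nx.gnp_random_graph(9, 0.35, seed=seed)
        pairs = [(f"G{a}", f"G{b}") for a, b in g.edges]
        net = _net(pairs, nodes=[f"G{i}" for i in range(9)])
        for v in sorted(net.nodes()):
            assert vertex_weight(net, v) == pytest.approx(
                ref_vertex_weight(net.nodes(), pairs, v)
            )


class TestPredictComplexes:
    def test_edgeless_graph_gives_no_clusters(self):
        net = _net([], nodes=["A", "B", "C"])
        assert predict_complexes(net) == []

    def test_clique_with_pendant_haircuts_to_clique(self):
        pairs, names = _k(5)
        clusters = predict_complexes(_net(pairs + [(names[0], "PENDANT")]))
        assert len(clusters) == 1
        assert clusters[0].members == set(names)
        assert clusters[0].score == pytest.approx(5.0)

    def test_two_bridged_equal_cliques_grow_together(self):
        """All eight vertices weigh 3, the inclusion threshold is 2.4, so
        growth crosses the bridge: one cluster of 8, density 13/28.
        Frozen from the naive reference implementation."""
        p1, n1 = _k(4, "A")
        p2, n2 = _k(4, "B")
        pairs = p1 + p2 + [(n1[0], n2[0])]
        clusters = predict_complexes(_net(pairs))
        ref = ref_predict([v for p in pairs for v in p], pairs)
        assert [(frozenset(c.members), c.seed, c.score) for c in clusters] == [
            (r[0], r[1], pytest.approx(r[2])) for r in ref
        ]
        assert len(clusters) == 1
        assert clusters[0].members == set(n1) | set(n2)
        assert clusters[0].score == pytest.approx(13 / 28 * 8)

    def test_disconnected_cliques_found_separately(self):
        p1, n1 = _k(5, "A")
        p2, n2 = _k(4, "B")
        clusters = predict_complexes(_net(p1 + p2))
        assert {frozenset(c.members) for c in clusters} == {
            frozenset(n1), frozenset(n2),
        }

    def test_emitted_clusters_contain_two_core(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=21)
        net = _net([(f"G{a}", f"G{b}") for a, b in g.edges])
        for c in predict_complexes(net):
            sub = net.graph.subgraph(c.members)
            assert max(nx.core_number(sub).values()) >= 2
            assert c.size >= 2
            assert 0 < c.density <= 1
            assert c.score <= c.size

    def test_invariant_to_edge_insertion_order(self, rng):
        g = nx.gnp_random_graph(12, 0.35, seed=8)
        pairs = [(f"G{a}", f"G{b}") for a, b in g.edges]
        base = predict_complexes(_net(pairs))
        perm = [pairs[i] for i in rng.permutation(len(pairs))]
        again = predict_complexes(_net(perm))
        assert [(c.members, c.seed) for c in base] == [
            (c.members, c.seed) for c in again
        ]

    def test_clusters_disjoint_without_fluff(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=13)
        clusters = predict_complexes(_net([(f"G{a}", f"G{b}") for a, b in g.edges]))
        seen = set()
        for c in clusters:
            assert not (c.members & seen)
            seen |= c.members

    @pytest.mark.parametrize("batch", range(5))
    def test_matches_reference_on_random_graphs(self, batch):
        """100 seeded random graphs per batch, n <= 9, vs the naive
        independently coded procedure."""
        for i in range(100):
            seed = batch * 100 + i
            n = 3 + seed % 7
            g = nx.gnp_random_graph(n, 0.15 + (seed % 8) / 10.0, seed=seed)
            pairs = [(f"G{a}", f"G{b}") for a, b in g.edges]
            net = _net(pairs, nodes=[f"G{i}" for i in range(n)])
            ours = [
                (frozenset(c.members), c.seed, round(c.score, 9))
                for c in predict_complexes(net)
            ]
            ref = [(m, s, round(sc, 9)) for m, s, sc in ref_predict(net.nodes(), pairs)]
            assert ours == ref, f"seed {seed}"


class TestFilterClusters:
    def _cluster(self, n, density):
        return Cluster(
            members={f"G{i}" for i in range(n)}, seed="G0",
            density=density, score=density * n,
        )

    def test_k4_kept_triangle_dropped(self):
        k4 = self._cluster(4, 1.0)
        tri = self._cluster(3, 1.0)
        assert filter_clusters([k4, tri]) == [k4]

    def test_boundary_score(self):
        low = self._cluster(4, 0.8)  # score 3.2 < 3.3
        at = self._cluster(4, 0.825)  # score 3.3 kept (inclusive)
        assert filter_clusters([low, at]) == [at]

    def test_against_predicate_oracle(self, rng):
        clusters = [
            self._cluster(int(rng.integers(2, 9)), float(rng.uniform(0.2, 1.0)))
            for _ in range(40)
        ]
        kept = filter_clusters(clusters)
        expected = [c for c in clusters if c.size >= 4 and c.score >= 3.3]
        assert {id(c) for c in kept} == {id(c) for c in expected}
        scores = [c.score for c in kept]
        assert scores == sorted(scores, reverse=True)


class TestExpandFirstNeighbors:
    def test_no_external_neighbors_is_identity(self):
        pairs, names = _k(4)
        net = _net(pairs)
        cluster = predict_complexes(net)[0]
        expanded = expand_first_neighbors(cluster, net)
        assert expanded.expanded_members == set(names)

    def test_two_pendants_on_one_member(self):
        pairs, names = _k(4)
        net = _net(pairs + [(names[0], "X1"), (names[0], "X2")])
        cluster = Cluster(members=set(names), seed=names[0], density=1.0, score=4.0)
        expanded = expand_first_neighbors(cluster, net)
        assert len(expanded.expanded_members) == 6
        assert expanded.members == set(names)

    def test_against_union_of_neighborhoods(self, rng):
        g = nx.gnp_random_graph(18, 0.2, seed=6)
        net = _net([(f"G{a}", f"G{b}") for a, b in g.edges])
        members = set(list(net.nodes())[:6])
        cluster = Cluster(members=members, seed=min(members), density=0.5, score=3.0)
        expanded = expand_first_neighbors(cluster, net)
        expected = set(members)
        for v in members:
            expected |= set(net.graph.neighbors(v))
        assert expanded.expanded_members == expected

    def test_members_outside_network_rejected(self):
        net = _net([("A", "B")])
        cluster = Cluster(members={"A", "Z"}, seed="A", density=1.0, score=2.0)
        with pytest.raises(ValidationError):
            expand_first_neighbors(cluster, net)


class TestParams:
    def test_invalid_vwp(self):
        with pytest.raises(ValidationError):
            McodeParams(node_score_cutoff=1.0)
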