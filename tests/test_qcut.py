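import networkx as nx
import numpy as np
import pytest

from oracles import blocks_to_partition, brute_force_max_q, set_partitions
from qcutnet.evalmetrics import adjusted_rand_index
from qcutnet.qcut import (
    modularity,
    qcut_partition,
    refine_partition,
    spectral_split,
)
from qcutnet.synthdata import planted_partition_graph


class TestModularity:
    def test_single_module_partition_is_exactly_zero(self, two_triangles_bridge):
        g = two_triangles_bridge
        assert modularity(g, {v: 1 for v in g}).q == 0.0

    def test_two_triangles_bridge_partition(self, two_triangles_bridge):
        part = {0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2}
        score = modularity(two_triangles_bridge, part)
        assert score.q == pytest.approx(5 / 14)
        assert score.per_module[1] == pytest.approx((3 / 7, 1 / 2))

    def test_all_singletons_partition(self, two_triangles_bridge):
        part = {v: i + 1 for i, v in enumerate(two_triangles_bridge)}
        assert modularity(two_triangles_bridge, part).q == pytest.approx(-34 / 196)

    def test_edgeless_network_is_an_error(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError, match="no edges"):
            modularity(g, {v: 1 for v in g})

    def test_incomplete_partition_is_an_error(self, two_triangles_bridge):
        with pytest.raises(ValueError, match="cover"):
            modularity(two_triangles_bridge, {0: 1})

    def test_uniform_weights_reduce_to_unweighted(self, two_cliques_bridge):
        part = {v: 1 if v < 5 else 2 for v in two_cliques_bridge}
        weighted = two_cliques_bridge.copy()
        nx.set_edge_attributes(weighted, 2.5, "weight")
        assert modularity(weighted, part).q == pytest.approx(
            modularity(two_cliques_bridge, part).q
        )

    def test_matches_networkx_on_random_graphs(self):
        """Independent cross-check of Eq-style Q against networkx."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            part = {v: int(rng.integers(1, 4)) for v in g}
            communities = [
                {v for v in g if part[v] == lab} for lab in set(part.values())
            ]
            assert modularity(g, part).q == pytest.approx(
                nx.community.modularity(g, communities)
            )

    def test_q_bounds_exhaustive_small_graphs(self):
        """Q in [-1, 1] over every partition of random graphs on <= 6 nodes."""
        rng = np.random.default_rng(1)
        for _ in range(8):
            g = nx.gnp_random_graph(int(rng.integers(4, 7)), 0.5, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            for blocks in set_partitions(list(g.nodes)):
                assert -1.0 <= modularity(g, blocks_to_partition(blocks)).q <= 1.0


class TestSpectralSplit:
    def test_two_cliques_split_along_bridge(self, two_cliques_bridge):
        labels, gain = spectral_split(two_cliques_bridge, seed=0)
        assert gain == pytest.approx(20 / 21 - 0.5)
        assert {frozenset(v for v in labels if labels[v] == s) for s in (1, 2)} == {
            frozenset(range(5)),
            frozenset(range(5, 10)),
        }

    def test_single_clique_is_not_split(self):
        labels, gain = spectral_split(nx.complete_graph(5), seed=0)
        assert labels is None and gain == 0.0

    def test_ring_of_three_cliques_prefers_three_way(self, three_cliques_ring):
        labels, gain = spectral_split(three_cliques_ring, seed=0)
        assert len(set(labels.values())) == 3
        assert gain == pytest.approx(30 / 33 - 1 / 3)

    def test_subset_without_internal_edges_returns_no_split(self, two_cliques_bridge):
        labels, gain = spectral_split(two_cliques_bridge, nodes=[0, 9], seed=0)
        assert labels is None and gain == 0.0


class TestRefinePartition:
    def test_misassigned_node_is_moved_back(self, two_cliques_bridge):
        part = {v: 1 if v < 5 else 2 for v in two_cliques_bridge}
        part[4] = 2  # misassign one clique member
        refined = refine_partition(two_cliques_bridge, part)
        assert {v for v in refined if refined[v] == refined[0]} == set(range(5))

    def test_optimal_partition_is_a_fixed_point(self, two_cliques_bridge):
        part = {v: 1 if v < 5 else 2 for v in two_cliques_bridge}
        refined = refine_partition(two_cliques_bridge, part)
        assert refined == part

    def test_bad_halves_of_k6_are_merged(self):
        k6 = nx.complete_graph(6)
        part = {v: 1 if v < 3 else 2 for v in k6}
        assert modularity(k6, part).q < 0
        refined = refine_partition(k6, part)
        assert len(set(refined.values())) == 1
        assert modularity(k6, refined).q == 0.0

    def test_never_decreases_q(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            part = {v: int(rng.integers(1, 5)) for v in g}
            refined = refine_partition(g, part, seed=int(rng.integers(2**31)))
            assert modularity(g, refined).q >= modularity(g, part).q - 1e-12

    def test_incremental_q_matches_from_scratch_after_each_operation(self):
        """The incremental Q bookkeeping agrees with full re-evaluation."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.25, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            part = {v: int(rng.integers(1, 6)) for v in g}
            log: list[tuple[float, float]] = []

            def audit(op, q_inc, snapshot, _g=g, _log=log):
                _log.append((q_inc, modularity(_g, snapshot).q))

            refine_partition(g, part, seed=0, on_accept=audit)
            assert log, "refinement accepted no operations on any graph"
            for q_inc, q_scratch in log:
                assert q_inc == pytest.approx(q_scratch, abs=1e-10)


class TestQcutPartition:
    def test_two_cliques(self, two_cliques_bridge):
        part, score = qcut_partition(two_cliques_bridge, seed=0)
        assert score.q == pytest.approx(20 / 21 - 0.5)
        assert len(set(part.values())) == 2

    def test_complete_graph_stays_whole(self):
        part, score = qcut_partition(nx.complete_graph(6), seed=0)
        assert len(set(part.values())) == 1
        assert score.q == 0.0

    def test_planted_partition_recovery(self):
        aris = []
        for seed in range(20):
            g, truth = planted_partition_graph([8] * 4, 0.9, 0.05, seed=seed)
            part, _ = qcut_partition(g, seed=seed)
            aris.append(adjusted_rand_index(truth, part))
        assert np.median(aris) >= 0.9

    def test_matches_exhaustive_maximum_on_most_small_graphs(self):
        rng = np.random.default_rng(4)
        hits = total = 0
        for _ in range(25):
            g = nx.gnp_random_graph(int(rng.integers(5, 9)), 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            total += 1
            best = brute_force_max_q(g)
            _, score = qcut_partition(g, seed=int(rng.integers(2**31)))
            assert score.q <= best + 1e-9  # heuristic can never beat exhaustive
            if score.q == pytest.approx(best, abs=1e-9):
                hits += 1
        assert hits / total >= 0.9

    def test_invariant_to_node_relabeling(self, three_cliques_ring):
        g = three_cliques_ring
        mapping = {v: f"x{v}" for v in g}
        part1, score1 = qcut_partition(g, seed=5)
        part2, score2 = qcut_partition(nx.relabel_nodes(g, mapping), seed=5)
        assert score1.q == pytest.approx(score2.q)
        renamed = {f"x{v}": lab for v, lab in part1.items()}
        assert adjusted_rand_index(renamed, part2) == pytest.approx(1.0)

    def test_disconnected_components_stay_separate(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part, _ = qcut_partition(g, seed=0)
        assert len(set(part.values())) == 2
        assert len({part[v] for v in range(4)}) == 1

    def test_deterministic_given_seed(self, three_cliques_ring):
        p1, s1 = qcut_partition(three_cliques_ring, seed=11)
        p2, s2 = qcut_partition(three_cliques_ring, seed=11)
        assert p1 == p2 and s1.q == s2.q
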