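import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from qcutnet.qcut import modularity
from qcutnet.refnet import (
    build_reference_network,
    idf_weight,
    propagate_and_filter,
    score_partition_on_reference,
    shuffle_partition_preserving_sizes,
)


def _attrs(rows: dict[str, list[int]], columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


class TestPropagateAndFilter:
    def test_annotation_propagates_to_ancestors(self):
        # T1 -> parent T2; g2 annotated to T2 only, so spans stay distinct
        attrs = _attrs({"g1": [1, 0], "g2": [0, 1]}, ["T1", "T2"])
        dag = nx.DiGraph([("T1", "T2")])
        out = propagate_and_filter(attrs, dag, min_size=1, max_size=10)
        assert out.loc["g1"].tolist() == [1, 1]  # g1 inherits the ancestor
        assert out.loc["g2"].tolist() == [0, 1]

    def test_closure_then_dedup_collapses_identical_spans(self):
        # sole annotation propagates, making T1 and T2 cover the same genes
        attrs = _attrs({"g1": [1, 0]}, ["T2", "T1"])
        dag = nx.DiGraph([("T2", "T1")])
        out = propagate_and_filter(attrs, dag, min_size=1, max_size=10)
        assert list(out.columns) == ["T1"]

    def test_duplicate_spans_keep_lexicographically_smallest(self):
        attrs = _attrs({"g1": [1, 1], "g2": [1, 1]}, ["T2", "T1"])
        out = propagate_and_filter(attrs, None, min_size=1, max_size=10)
        assert list(out.columns) == ["T1"]

    def test_size_filter_applies_after_closure(self):
        attrs = _attrs(
            {f"g{i}": [1 if i < 2 else 0, 1] for i in range(6)}, ["small", "big"]
        )
        out = propagate_and_filter(attrs, None, min_size=5, max_size=500)
        assert list(out.columns) == ["big"]


class TestIdfWeight:
    def test_universal_attribute_gets_zero_weight(self):
        attrs = _attrs({"g1": [1], "g2": [1], "g3": [1]}, ["T"])
        assert idf_weight(attrs)["T"].tolist() == [0.0, 0.0, 0.0]

    def test_half_coverage_gives_ln2(self):
        attrs = _attrs({"g1": [1], "g2": [1], "g3": [0], "g4": [0]}, ["T"])
        assert idf_weight(attrs).loc["g1", "T"] == pytest.approx(math.log(2))

    def test_single_coverage_is_maximal(self):
        attrs = _attrs({f"g{i}": [1 if i == 0 else 0, 1] for i in range(5)}, ["rare", "all"])
        w = idf_weight(attrs)
        assert w.loc["g0", "rare"] == pytest.approx(math.log(5))

    def test_zero_coverage_attribute_is_an_error(self):
        attrs = _attrs({"g1": [1, 0], "g2": [1, 0]}, ["T1", "T2"])
        with pytest.raises(ValueError, match="covers no entity"):
            idf_weight(attrs)


class TestBuildReferenceNetwork:
    def test_identical_rows_get_weight_one(self):
        attrs = _attrs({"g1": [1, 1], "g2": [1, 1], "g3": [1, 0], "g4": [0, 0]},
                       ["A", "B"])
        ref = build_reference_network(idf_weight(attrs), 0.0)
        assert ref.edges["g1", "g2"]["weight"] == pytest.approx(1.0)

    def test_disjoint_attribute_sets_are_unconnected(self):
        attrs = _attrs({"g1": [1, 0], "g2": [0, 1], "g3": [1, 0], "g4": [0, 1]},
                       ["A", "B"])
        ref = build_reference_network(idf_weight(attrs), 0.0)
        assert not ref.has_edge("g1", "g2")
        assert ref.has_edge("g1", "g3")

    def test_hand_computed_cosine(self):
        # n=4: g1 {A,B}, g2 {B,C}; idf(A)=idf(C)=ln4, idf(B)=ln2 -> cos = 0.2
        attrs = _attrs(
            {"g1": [1, 1, 0], "g2": [0, 1, 1], "g3": [0, 0, 0], "g4": [0, 0, 0]},
            ["A", "B", "C"],
        )
        ref = build_reference_network(idf_weight(attrs), 0.0)
        assert ref.edges["g1", "g2"]["weight"] == pytest.approx(0.2)

    def test_cosine_invariant_to_idf_log_base(self):
        rng = np.random.default_rng(0)
        attrs = pd.DataFrame(
            rng.integers(0, 2, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"T{j}" for j in range(6)],
        )
        attrs = attrs.loc[:, attrs.sum(axis=0) > 0]
        w_nat = idf_weight(attrs)
        w_base2 = w_nat / math.log(2)  # uniform rescaling = changing log base
        for cut in (0.0, 0.3):
            r1 = build_reference_network(w_nat, cut)
            r2 = build_reference_network(w_base2, cut)
            assert set(r1.edges) == set(r2.edges)
            for u, v in r1.edges:
                assert r1.edges[u, v]["weight"] == pytest.approx(r2.edges[u, v]["weight"])

    def test_edge_set_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(1)
        attrs = pd.DataFrame(
            rng.integers(0, 2, size=(15, 8)),
            index=[f"g{i}" for i in range(15)],
            columns=[f"T{j}" for j in range(8)],
        )
        attrs = attrs.loc[:, attrs.sum(axis=0) > 0]
        w = idf_weight(attrs)
        prev = None
        for cut in (0.0, 0.2, 0.4, 0.6, 0.8):
            edges = set(build_reference_network(w, cut).edges)
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestScorePartitionOnReference:
    def test_consistency_with_plain_modularity(self, two_cliques_bridge):
        part = {v: 1 if v < 5 else 2 for v in two_cliques_bridge}
        assert score_partition_on_reference(two_cliques_bridge, part).q == pytest.approx(
            modularity(two_cliques_bridge, part).q
        )

    def test_perfect_agreement_with_equal_modules(self):
        # 4 equal-weight modules, all reference edges internal -> 1 - 4*(1/4)^2
        ref = nx.Graph()
        part = {}
        for m in range(4):
            a, b = f"a{m}", f"b{m}"
            ref.add_edge(a, b, weight=1.0)
            part[a] = part[b] = m + 1
        assert score_partition_on_reference(ref, part).q == pytest.approx(0.75)

    def test_partition_entities_missing_from_reference_are_ignored(self):
        ref = nx.Graph()
        ref.add_edge("g1", "g2", weight=1.0)
        part = {"g1": 1, "g2": 1, "g3": 2, "g4": 2}  # g3,g4 not in reference
        assert score_partition_on_reference(ref, part).q == 0.0

    def test_shuffled_partitions_score_near_zero(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(120)]
        truth = {g: i // 20 + 1 for i, g in enumerate(genes)}
        inc = np.zeros((120, 6), dtype=int)
        for i, g in enumerate(genes):
            if rng.random() < 0.9:
                inc[i, truth[g] - 1] = 1
        attrs = pd.DataFrame(inc, index=genes, columns=[f"T{j}" for j in range(6)])
        ref = build_reference_network(idf_weight(attrs), 0.1)
        true_score = score_partition_on_reference(ref, truth).q
        shuffled = [
            score_partition_on_reference(
                ref, shuffle_partition_preserving_sizes(truth, seed=s)
            ).q
            for s in range(100)
        ]
        assert true_score >= 0.3
        assert abs(np.mean(shuffled)) < 0.02


class TestShufflePreservingSizes:
    def test_module_sizes_preserved_and_deterministic(self):
        part = {f"n{i}": lab for i, lab in enumerate([1] * 3 + [2] * 5 + [3] * 7)}
        shuf = shuffle_partition_preserving_sizes(part, seed=0)
        assert sorted(np.bincount(list(shuf.values()))[1:]) == [3, 5, 7]
        assert shuf == shuffle_partition_preserving_sizes(part, seed=0)

    def test_two_node_swap_is_uniform(self):
        part = {"a": 1, "b": 2}
        swaps = sum(
            shuffle_partition_preserving_sizes(part, seed=s)["a"] == 2
            for s in range(1000)
        )
        assert 420 <= swaps <= 580  # ~Binomial(1000, 1/2)
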