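"""Median-joining network construction and export."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from ypopgen import (
    CharacterSet,
    build_mj_network,
    export_network,
    haplotype_classes,
    quasi_median,
    star_contraction,
    weighted_distance,
)
from ypopgen.network import _mst_cost, step_distance


def binary_chars(k, weight=1):
    return CharacterSet(
        names=tuple(f"c{i}" for i in range(k)),
        weights=(float(weight),) * k,
        is_snp=(False,) * k,
    )


def snp_chars(k):
    return CharacterSet(
        names=tuple(f"s{i}" for i in range(k)),
        weights=(99.0,) * k,
        is_snp=(True,) * k,
    )


class TestWeightedDistance:
    def test_identical_is_zero(self):
        chars = binary_chars(3)
        assert weighted_distance((1, 2, 3), (1, 2, 3), chars) == 0.0

    def test_str_weighting(self):
        chars = CharacterSet(names=("a", "b"), weights=(3.0, 1.0), is_snp=(False, False))
        assert weighted_distance((10, 10), (12, 10), chars) == 6.0

    def test_snp_weight_99(self):
        chars = CharacterSet(names=("a", "s"), weights=(2.0, 99.0), is_snp=(False, True))
        assert weighted_distance((10, 0), (10, 1), chars) == 99.0

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            weighted_distance((1, 2), (1, 2, 3), binary_chars(3))


class TestQuasiMedian:
    def test_str_median_componentwise(self):
        chars = binary_chars(2)
        assert quasi_median((10, 10), (11, 10), (10, 11), chars) == (10, 10)

    def test_snp_majority(self):
        chars = snp_chars(3)
        assert quasi_median((0, 0, 0), (1, 1, 0), (1, 0, 1), chars) == (1, 0, 0)


class TestBuild:
    def test_two_classes_single_edge(self):
        chars = binary_chars(2)
        net = build_mj_network([(10, 10), (11, 10)], chars)
        assert len(net.graph.nodes) == 2 and len(net.graph.edges) == 1
        assert net.medians == []

    def test_steiner_median_shortens_network(self):
        """Three binary haplotypes: one median turns cost 4 into cost 3."""
        chars = binary_chars(3)
        classes = [(0, 0, 0), (1, 1, 0), (1, 0, 1)]
        assert _mst_cost([tuple(map(float, c)) for c in classes], chars) == 4.0
        net = build_mj_network(classes, chars)
        assert net.medians == [(1.0, 0.0, 0.0)]
        assert net.total_length() == 3.0
        assert net.graph.degree[(1.0, 0.0, 0.0)] == 3

    def test_star_through_existing_node(self):
        chars = binary_chars(2)
        net = build_mj_network([(10, 10), (11, 10), (10, 11)], chars)
        assert net.medians == []
        assert net.graph.degree[(10.0, 10.0)] == 2

    def test_contains_spanning_tree_of_final_nodes(self, rng):
        """The network always contains an MST over its final node set."""
        for _ in range(20):
            k = rng.integers(3, 8)
            vecs = {tuple(rng.integers(0, 3, size=4).astype(float)) for _ in range(k)}
            chars = binary_chars(4)
            net = build_mj_network(sorted(vecs), chars)
            g = net.graph
            assert nx.is_connected(g)
            nodes = sorted(g.nodes)
            mst_cost = _mst_cost(nodes, chars)
            sub_cost = nx.minimum_spanning_tree(g, weight="length").size(weight="length")
            assert sub_cost == pytest.approx(mst_cost)

    def test_order_invariance(self, rng):
        chars = binary_chars(4)
        vecs = sorted({tuple(rng.integers(0, 3, size=4).astype(float)) for _ in range(6)})
        net1 = build_mj_network(vecs, chars)
        perm = list(vecs)[::-1]
        net2 = build_mj_network(perm, chars)
        assert sorted(net1.graph.nodes) == sorted(net2.graph.nodes)
        assert sorted(map(sorted, net1.graph.edges)) == sorted(map(sorted, net2.graph.edges))

    def test_cost_never_above_observed_mst(self, rng):
        chars = binary_chars(5)
        for _ in range(10):
            vecs = sorted({tuple(rng.integers(0, 2, size=5).astype(float)) for _ in range(6)})
            net = build_mj_network(vecs, chars)
            observed_cost = _mst_cost(vecs, chars)
            final_cost = _mst_cost(sorted(net.graph.nodes), chars)
            assert final_cost <= observed_cost + 1e-9

    def test_duplicate_classes_rejected(self):
        chars = binary_chars(2)
        with pytest.raises(ValueError, match="merged"):
            build_mj_network([(1, 1), (1, 1)], chars)


class TestStarContraction:
    def test_leaves_merge_into_hub(self):
        chars = binary_chars(2)
        classes = [((10.0, 10.0), 5), ((11.0, 10.0), 1), ((10.0, 11.0), 1)]
        merged = star_contraction(classes, chars, delta=1.0)
        assert merged == [((10.0, 10.0), 7)]

    def test_distant_classes_survive(self):
        chars = binary_chars(2)
        classes = [((10.0, 10.0), 5), ((15.0, 15.0), 2)]
        assert star_contraction(classes, chars, delta=1.0) == sorted(classes)


class TestDatasetClasses:
    def test_classes_merge_and_compose(self, sim_dataset):
        ds, _, snp_states = sim_dataset
        # convert states to binary for the network characters
        binary = {
            sid: {snp: 1 if st == "D" else 0 for snp, st in states.items()}
            for sid, states in snp_states.items()
        }
        classes, chars, comp = haplotype_classes(ds, snp_states=binary)
        assert sum(m for _, m in classes) == len(ds)
        assert chars.n == len(ds.panel.single_copy) + len(next(iter(binary.values())))
        total_comp = sum(sum(c.values()) for c in comp.values())
        assert total_comp == len(ds)


class TestExport:
    def test_edge_tsv_and_graphml_round_trip(self, tmp_path):
        chars = binary_chars(3)
        net = build_mj_network(
            [((0.0, 0.0, 0.0), 3), ((1.0, 1.0, 0.0), 2), ((1.0, 0.0, 1.0), 1)],
            chars,
            composition={(0.0, 0.0, 0.0): {"Han": 2, "Hui": 1}},
        )
        tsv = tmp_path / "net.tsv"
        export_network(net, tsv, fmt="edge_tsv")
        lines = tsv.read_text().strip().split("\n")
        assert len(lines) == 1 + net.graph.number_of_edges()

        gml = tmp_path / "net.graphml"
        export_network(net, gml, fmt="graphml")
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == net.graph.number_of_nodes()
        assert back.number_of_edges() == net.graph.number_of_edges()
        comps = nx.get_node_attributes(back, "composition")
        assert "Han:2;Hui:1" in comps.values()

    def test_unknown_format_rejected(self, tmp_path):
        chars = binary_chars(2)
        net = build_mj_network([(0.0, 0.0), (1.0, 0.0)], chars)
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", fmt="nexus")
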