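"""Detector behaviour, partition invariants and modularity."""

import networkx as nx
import numpy as np
import pytest
from oracles import modularity_double_sum

from conftest import clique_graph, network_from_edges
from ppimodules.detection import (
    ConfigurationError,
    DegenerateInputError,
    ModulePartition,
    TopologicalModule,
    detect_modules,
    mcl_cluster,
    modularity,
    read_partition,
    rwr_cluster,
    write_partition,
)
from ppimodules.netio import ProteinNetwork


class TestModularity:
    def test_whole_graph_one_module_is_zero(self, two_triangles):
        part = ModulePartition(
            [TopologicalModule(0, frozenset(two_triangles.proteins))], two_triangles
        )
        assert modularity(two_triangles, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_half(self, two_triangles, two_triangle_partition):
        assert modularity(two_triangles, two_triangle_partition) == pytest.approx(0.5)

    def test_k4_split_into_pairs(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        net = ProteinNetwork(graph=g)
        part = ModulePartition(
            [TopologicalModule(0, frozenset({"0", "1"})),
             TopologicalModule(1, frozenset({"2", "3"}))],
            net,
        )
        assert modularity(net, part) == pytest.approx(-1 / 6, abs=1e-12)

    def test_nodes_outside_modules_count_as_singletons(self, two_triangles):
        # dropping one triangle from the partition must equal the
        # partition where its nodes are explicit singletons
        part = ModulePartition(
            [TopologicalModule(0, frozenset({"a1", "a2", "a3"}))], two_triangles
        )
        explicit = ModulePartition(
            [TopologicalModule(0, frozenset({"a1", "a2", "a3"})),
             TopologicalModule(1, frozenset({"b1"})),
             TopologicalModule(2, frozenset({"b2"})),
             TopologicalModule(3, frozenset({"b3"}))],
            two_triangles,
        )
        assert modularity(two_triangles, part) == pytest.approx(
            modularity(two_triangles, explicit), abs=1e-12
        )

    def test_edgeless_network_raises(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        with pytest.raises(DegenerateInputError):
            modularity(
                ProteinNetwork(graph=g),
                ModulePartition([TopologicalModule(0, frozenset("A"))],
                                ProteinNetwork(graph=g)),
            )

    def test_matches_double_sum_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, str)
            if g.number_of_edges() == 0:
                continue
            labels = {v: int(rng.integers(4)) for v in g.nodes}
            groups: dict[int, set] = {}
            for v, c in labels.items():
                groups.setdefault(c, set()).add(v)
            net = ProteinNetwork(graph=g)
            part = ModulePartition(
                [TopologicalModule(i, frozenset(s))
                 for i, s in enumerate(groups.values())],
                net,
            )
            assert modularity(net, part) == pytest.approx(
                modularity_double_sum(g, labels), abs=1e-12
            )

    def test_range_bounds_on_random_partitions(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.relabel_nodes(nx.gnp_random_graph(20, 0.3, seed=int(rng.integers(2**31))), str)
            if g.number_of_edges() == 0:
                continue
            net = ProteinNetwork(graph=g)
            labels = {v: int(rng.integers(5)) for v in g.nodes}
            groups: dict[int, set] = {}
            for v, c in labels.items():
                groups.setdefault(c, set()).add(v)
            part = ModulePartition(
                [TopologicalModule(i, frozenset(s))
                 for i, s in enumerate(groups.values())],
                net,
            )
            assert -0.5 <= modularity(net, part) < 1.0


class TestDefaultDetector:
    def test_two_disjoint_cliques_found_as_modules(self):
        net = clique_graph(2, 4)
        part = detect_modules(net, "default")
        assert {frozenset(m.proteins) for m in part.modules} == {
            frozenset(c) for c in nx.connected_components(net.graph)
        }

    def test_single_triangle_one_module(self):
        net = network_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        part = detect_modules(net, "default")
        assert len(part.modules) == 1 and len(part.modules[0]) == 3

    def test_deterministic_for_fixed_seed(self, synth_bundle):
        net = synth_bundle["network"]
        p1 = detect_modules(net, "default", seed=5)
        p2 = detect_modules(net, "default", seed=5)
        assert [m.proteins for m in p1.modules] == [m.proteins for m in p2.modules]

    def test_covers_every_node(self, synth_bundle):
        net = synth_bundle["network"]
        part = detect_modules(net, "default")
        assert set(part.labels()) == net.proteins

    def test_unknown_method_rejected(self, two_triangles):
        with pytest.raises(ConfigurationError):
            detect_modules(two_triangles, "walktrap")


class TestMCL:
    def test_two_disjoint_triangles_two_clusters(self, two_triangles):
        part = mcl_cluster(two_triangles, inflation=2.0)
        assert {frozenset(m.proteins) for m in part.modules} == {
            frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})
        }

    def test_isolated_node_becomes_singleton(self):
        g = nx.Graph()
        g.add_node("x")
        part = mcl_cluster(ProteinNetwork(graph=g))
        assert [set(m.proteins) for m in part.modules] == [{"x"}]

    def test_triangle_plus_isolated_node(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_node("z")
        part = mcl_cluster(ProteinNetwork(graph=g))
        assert {frozenset(m.proteins) for m in part.modules} == {
            frozenset({"a", "b", "c"}), frozenset({"z"})
        }

    def test_covers_every_node_disjointly(self, synth_bundle):
        net = synth_bundle["network"]
        part = mcl_cluster(net)
        labels = part.labels()
        assert set(labels) == net.proteins  # disjointness enforced by type

    def test_inflation_must_exceed_one(self, two_triangles):
        with pytest.raises(ConfigurationError):
            mcl_cluster(two_triangles, inflation=1.0)


class TestRWR:
    def test_one_seed_per_triangle(self, two_triangles):
        part = rwr_cluster(two_triangles, seeds={"a1", "b2"})
        assert {frozenset(m.proteins) for m in part.modules} == {
            frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})
        }

    def test_seed_assigned_to_itself(self, two_triangles):
        part = rwr_cluster(two_triangles, seeds={"a1", "a2"})
        labels = part.labels()
        by_id = {m.module_id: m for m in part.modules}
        assert "a1" in by_id[labels["a1"]].proteins
        assert "a2" in by_id[labels["a2"]].proteins
        assert labels["a1"] != labels["a2"]

    def test_symmetric_node_goes_to_lexicographically_smaller_seed(self):
        # path a - m - b: m is exactly symmetric between seeds a and b
        net = network_from_edges([("a", "m"), ("m", "b")])
        part = rwr_cluster(net, seeds={"a", "b"})
        labels = part.labels()
        assert labels["m"] == labels["a"]

    def test_unreachable_node_goes_to_unassigned_module(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b")])
        g.add_node("z")
        part = rwr_cluster(ProteinNetwork(graph=g), seeds={"a"})
        assert part.unassigned_id is not None
        by_id = {m.module_id: m for m in part.modules}
        assert by_id[part.unassigned_id].proteins == frozenset({"z"})

    def test_empty_or_foreign_seeds_rejected(self, two_triangles):
        with pytest.raises(ConfigurationError):
            rwr_cluster(two_triangles, seeds=set())
        with pytest.raises(ConfigurationError):
            rwr_cluster(two_triangles, seeds={"nope"})


class TestPartition:
    def test_large_small_split_at_three(self, two_triangles):
        part = ModulePartition(
            [TopologicalModule(0, frozenset({"a1", "a2", "a3"})),
             TopologicalModule(1, frozenset({"b1", "b2"})),
             TopologicalModule(2, frozenset({"b3"}))],
            two_triangles,
        )
        assert [m.module_id for m in part.large_modules()] == [0]
        assert [m.module_id for m in part.small_modules()] == [1, 2]

    def test_overlapping_modules_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            ModulePartition(
                [TopologicalModule(0, frozenset({"a1", "a2"})),
                 TopologicalModule(1, frozenset({"a2", "a3"}))],
                two_triangles,
            )

    def test_partition_tsv_round_trip(self, tmp_path, two_triangles, two_triangle_partition):
        path = tmp_path / "partition.tsv"
        write_partition(two_triangle_partition, path)
        back = read_partition(path, two_triangles)
        assert {m.proteins for m in back.modules} == {
            m.proteins for m in two_triangle_partition.modules
        }
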