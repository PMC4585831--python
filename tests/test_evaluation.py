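"""Mapping-frequency metrics, benchmark protocol and detector comparison."""

import pytest

from conftest import clique_graph
from ppimodules.detection import (
    DegenerateInputError,
    ModulePartition,
    TopologicalModule,
)
from ppimodules.enrichment import AnnotationSet, TermRecord
from ppimodules.evaluation import (
    AnnotationLayers,
    analyze_partition,
    average_mapping_frequency,
    build_benchmark_network,
    compare_methods,
    mapping_frequency,
    report_from_analysis,
)
from ppimodules.layers import DiseaseClassMap, LayerModule
from ppimodules.netio import InteractionRecord


def lm(layer, genes, parent, term="T"):
    return LayerModule(layer, parent, frozenset(genes), term)


def partition_of(network, *gene_groups):
    return ModulePartition(
        [TopologicalModule(i, frozenset(g)) for i, g in enumerate(gene_groups)],
        network,
    )


@pytest.fixture
def four_module_partition(synth_bundle):
    truth = synth_bundle["truth"]
    mods = truth.planted_partition.modules[:4]
    return ModulePartition(list(mods), synth_bundle["network"]), mods


class TestMappingFrequency:
    def test_three_of_four_mapped(self, four_module_partition):
        part, mods = four_module_partition
        calls = {
            m.module_id: [lm("disease", sorted(m.proteins)[:3], m.module_id, "Bone")]
            for m in mods[:3]
        }
        assert mapping_frequency(part, calls, "disease") == 0.75

    def test_all_mapped_is_one(self, four_module_partition):
        part, mods = four_module_partition
        calls = {
            m.module_id: [lm("functional", sorted(m.proteins)[:3], m.module_id)]
            for m in mods
        }
        assert mapping_frequency(part, calls, "functional") == 1.0

    def test_fully_covered_mode_uses_flags(self, four_module_partition):
        part, mods = four_module_partition
        flags = {m.module_id: m.module_id % 2 == 0 for m in mods}
        assert mapping_frequency(
            part, {}, "functional", mode="fully_covered", fully_covered=flags
        ) == 0.5

    def test_fully_covered_never_exceeds_mapped(self, synth_bundle):
        part = synth_bundle["truth"].planted_partition
        analysis = analyze_partition(
            part,
            AnnotationLayers(
                functional=synth_bundle["functional"],
                gene_diseases=synth_bundle["gene_diseases"],
                class_map=synth_bundle["class_map"],
            ),
        )
        mapped = mapping_frequency(part, analysis.layer_calls, "functional")
        covered = mapping_frequency(
            part, analysis.layer_calls, "functional",
            mode="fully_covered", fully_covered=analysis.fully_covered,
        )
        assert covered <= mapped

    def test_no_large_modules_raises(self, two_triangles):
        part = partition_of(two_triangles, {"a1", "a2"})
        with pytest.raises(DegenerateInputError):
            mapping_frequency(part, {}, "disease")


class TestAverageMappingFrequency:
    def test_single_fully_covered_module(self, four_module_partition):
        part, mods = four_module_partition
        part = ModulePartition([mods[0]], part.network_ref)
        calls = {mods[0].module_id: [lm("functional", mods[0].proteins, mods[0].module_id)]}
        assert average_mapping_frequency(part, calls, "functional") == 1.0

    def test_small_modules_excluded_best_coverage_used(self, two_triangles):
        # module 0 is large (4 nodes, best coverage 3/4); module 1 is
        # small and must not enter the mean
        part = partition_of(two_triangles, {"a1", "a2", "a3", "b1"}, {"b2", "b3"})
        calls = {0: [lm("functional", {"a1", "a2", "a3"}, 0)]}
        assert average_mapping_frequency(part, calls, "functional") == 0.75

    def test_two_modules_one_unmapped(self, synth_bundle):
        truth = synth_bundle["truth"]
        m0, m1 = truth.planted_partition.modules[:2]
        part = ModulePartition([m0, m1], synth_bundle["network"])
        calls = {m0.module_id: [lm("functional", sorted(m0.proteins)[:6], m0.module_id)]}
        assert average_mapping_frequency(part, calls, "functional") == pytest.approx(
            (6 / 8 + 0.0) / 2
        )

    def test_all_unmapped_is_zero(self, four_module_partition):
        part, _ = four_module_partition
        assert average_mapping_frequency(part, {}, "functional") == 0.0

    def test_never_exceeds_mapped_frequency(self, synth_bundle):
        part = synth_bundle["truth"].planted_partition
        analysis = analyze_partition(
            part,
            AnnotationLayers(
                functional=synth_bundle["functional"],
                pathways=synth_bundle["pathways"],
                gene_diseases=synth_bundle["gene_diseases"],
                class_map=synth_bundle["class_map"],
                complexes=synth_bundle["complexes"],
            ),
        )
        for layer in ("functional", "pathway", "disease", "complex"):
            avg = average_mapping_frequency(part, analysis.layer_calls, layer)
            mapped = mapping_frequency(part, analysis.layer_calls, layer)
            assert avg <= mapped + 1e-12


class TestBenchmarkNetwork:
    def records(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"),
                 ("e", "f"), ("f", "g"), ("g", "h"), ("h", "i"), ("i", "j")]
        return [
            InteractionRecord(x, y, 1.0, frozenset({"D1", "D2"}), "direct physical")
            for x, y in pairs
        ]

    def test_keeps_exactly_disease_touching_edges(self):
        disease_genes = {"a", "e"}
        net = build_benchmark_network(self.records(), disease_genes)
        # edges touching a or e: (a,b),(a,c),(d,e),(e,f) -> 4 edges
        assert net.n_edges == 4
        assert all(
            "a" in e or "e" in e for e in net.edges
        )

    def test_predicate_count_on_synthetic_records(self):
        disease_genes = {"c", "f", "i"}
        net = build_benchmark_network(self.records(), disease_genes)
        expected = sum(
            1 for r in self.records()
            if r.protein_a in disease_genes or r.protein_b in disease_genes
        )
        assert net.n_edges == expected == 7

    def test_empty_disease_set_rejected(self):
        with pytest.raises(ValueError):
            build_benchmark_network(self.records(), set())

    def test_untouched_network_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_benchmark_network(self.records(), {"zzz"})


class TestCompareMethods:
    def make_layers(self, net):
        cliques = [frozenset(f"c{c}n{i}" for i in range(4)) for c in range(2)]
        functional = AnnotationSet({
            f"T{c}": TermRecord(f"T{c}", "BP", 3, genes)
            for c, genes in enumerate(cliques)
        })
        return AnnotationLayers(functional=functional)

    def test_two_planted_cliques_with_covering_terms(self):
        net = clique_graph(2, 4)
        layers = self.make_layers(net)
        (report,) = compare_methods(net, [{"name": "default"}], layers)
        assert report.Q == pytest.approx(0.5)
        assert report.mapping_freq["functional"] == 1.0
        assert report.fully_covered_freq == 1.0

    def test_same_seed_gives_identical_reports(self, synth_bundle):
        net = synth_bundle["network"]
        layers = AnnotationLayers(
            functional=synth_bundle["functional"],
            gene_diseases=synth_bundle["gene_diseases"],
            class_map=synth_bundle["class_map"],
        )
        r1 = compare_methods(net, [{"name": "default"}, {"name": "rwr"}], layers, seed=3)
        r2 = compare_methods(net, [{"name": "default"}, {"name": "rwr"}], layers, seed=3)
        assert [(r.method_name, r.Q, r.mapping_freq) for r in r1] == [
            (r.method_name, r.Q, r.mapping_freq) for r in r2
        ]

    def test_three_methods_three_reports(self):
        net = clique_graph(3, 4)
        reports = compare_methods(
            net, [{"name": "default"}, {"name": "mcl"}, {"name": "rwr"}],
            self.make_layers(net), seed=1,
        )
        assert [r.method_name for r in reports] == ["default", "mcl", "rwr"]

    def test_failing_method_skipped_others_reported(self):
        net = clique_graph(2, 4)
        reports = compare_methods(
            net, [{"name": "nope"}, {"name": "default"}], self.make_layers(net)
        )
        assert [r.method_name for r in reports] == ["default"]

    def test_no_methods_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            compare_methods(two_triangles, [], AnnotationLayers())


def test_report_counts_bounded_by_mapped_modules(synth_bundle):
    # structural sanity: non-trivial <= modules with disease modules,
    # significant <= modules with pathway modules
    part = synth_bundle["truth"].planted_partition
    analysis = analyze_partition(
        part,
        AnnotationLayers(
            functional=synth_bundle["functional"],
            pathways=synth_bundle["pathways"],
            gene_diseases=synth_bundle["gene_diseases"],
            class_map=synth_bundle["class_map"],
        ),
    )
    report = report_from_analysis(synth_bundle["network"], analysis)
    n_large = report.n_modules_large
    assert report.n_non_trivial <= report.mapping_freq["disease"] * n_large + 1e-9
    assert report.n_significant <= report.mapping_freq["pathway"] * n_large + 1e-9
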