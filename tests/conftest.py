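import networkx as nx
import pytest

from ppimodules.detection import ModulePartition, TopologicalModule
from ppimodules.netio import ProteinNetwork
from ppimodules.synthgen import SynthConfig, generate_dataset


def network_from_edges(edges) -> ProteinNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return ProteinNetwork(graph=g)


def clique_graph(n_cliques: int, size: int = 4) -> ProteinNetwork:
    """Disjoint cliques c0n0..c0n{size-1}, c1n0, ..."""
    g = nx.Graph()
    for c in range(n_cliques):
        nodes = [f"c{c}n{i}" for i in range(size)]
        g.add_edges_from(
            (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
        )
    return ProteinNetwork(graph=g)


@pytest.fixture
def two_triangles() -> ProteinNetwork:
    return network_from_edges(
        [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
         ("b1", "b2"), ("b2", "b3"), ("b1", "b3")]
    )


@pytest.fixture
def two_triangle_partition(two_triangles) -> ModulePartition:
    return ModulePartition(
        modules=[
            TopologicalModule(0, frozenset({"a1", "a2", "a3"})),
            TopologicalModule(1, frozenset({"b1", "b2", "b3"})),
        ],
        network_ref=two_triangles,
    )


@pytest.fixture(scope="session")
def synth_bundle():
    """One generated dataset at the default study conditions (seed 0)."""
    config = SynthConfig(seed=0)
    network, truth, functional, pathways, gene_diseases, class_map, complexes = (
        generate_dataset(config)
    )
    return {
        "config": config,
        "network": network,
        "truth": truth,
        "functional": functional,
        "pathways": pathways,
        "gene_diseases": gene_diseases,
        "class_map": class_map,
        "complexes": complexes,
    }
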