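"""Cross-layer networks and non-trivial / significant classification.

A topological module is *non-trivial* when one of its disease modules
overlaps one of its functional modules on more than half of the disease
module's proteins, and *significant* when the same holds with a pathway
module in place of the functional module.  The overlap fraction is
|D ∩ F| / |D| with the disease module in the denominator, and "over
half" is strict (an exact 0.5 overlap does not qualify).

This module also builds the bipartite protein-term networks (one edge
per gene of a layer module to its supporting term or class) and the
disease-disease network that links two diseases whenever they share a
disease gene, either inside one topological module or globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from ppimodules.detection import TopologicalModule
from ppimodules.layers import LayerModule


@dataclass
class BipartiteLayerNetwork:
    """Bipartite protein-to-term (or disease class) association network."""

    left_nodes: set[str] = field(default_factory=set)  # proteins
    right_nodes: set[str] = field(default_factory=set)  # terms / classes
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g, t in self.edges:
            if g not in self.left_nodes or t not in self.right_nodes:
                raise ValueError(f"edge ({g}, {t}) endpoints not in node sets")

    def degree(self, protein: str) -> int:
        return sum(1 for g, _ in self.edges if g == protein)


@dataclass
class DiseaseDiseaseNetwork:
    """Diseases linked when they share at least one disease gene."""

    diseases: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)
    shared_genes: dict[frozenset[str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if not self.shared_genes.get(e):
                raise ValueError("every disease-disease edge needs shared genes")


@dataclass(frozen=True)
class ModuleClassification:
    """Per-topological-module verdicts."""

    module_id: int
    mapped_functional: bool
    fully_covered: bool
    mapped_pathway: bool
    mapped_disease: bool
    non_trivial: bool
    significant: bool

    def __post_init__(self) -> None:
        if self.non_trivial and not (self.mapped_disease and self.mapped_functional):
            raise ValueError("non-trivial requires disease and functional modules")
        if self.significant and not (self.mapped_disease and self.mapped_pathway):
            raise ValueError("significant requires disease and pathway modules")


def overlap_fraction(disease_module: LayerModule, other: LayerModule) -> float:
    """|genes(disease) ∩ genes(other)| / |genes(disease)|.

    The disease module's size is the denominator, so the fraction is 1
    exactly when the disease module is contained in the other module.
    """
    if disease_module.parent_module_id != other.parent_module_id:
        raise ValueError("overlap is defined within one topological module")
    if not disease_module.genes:
        raise ValueError("empty disease module")
    return len(disease_module.genes & other.genes) / len(disease_module.genes)


def classify_module(
    module: TopologicalModule,
    functional: list[LayerModule],
    pathway: list[LayerModule],
    disease: list[LayerModule],
    threshold: float = 0.5,
    fully_covered: bool = False,
) -> ModuleClassification:
    """Classify one topological module from its layer calls.

    Non-trivial iff some disease module overlaps some functional module
    strictly above ``threshold`` (default 0.5, i.e. "over half");
    significant iff the same holds against a pathway module.
    """
    non_trivial = any(
        overlap_fraction(d, f) > threshold for d in disease for f in functional
    )
    significant = any(
        overlap_fraction(d, p) > threshold for d in disease for p in pathway
    )
    return ModuleClassification(
        module_id=module.module_id,
        mapped_functional=bool(functional),
        fully_covered=fully_covered,
        mapped_pathway=bool(pathway),
        mapped_disease=bool(disease),
        non_trivial=non_trivial,
        significant=significant,
    )


def build_disease_disease_network(
    modules: list[TopologicalModule],
    gene_diseases: dict[str, set[str]],
    scope: int | str = "global",
) -> DiseaseDiseaseNetwork:
    """Disease-disease network over one module's genes or all of them.

    ``scope`` is a module id or ``"global"``.  Nodes are the diseases hit
    by at least one in-scope gene; two diseases are linked when some
    in-scope gene is associated with both, and the sharing genes are
    recorded per edge.
    """
    if scope == "global":
        genes: set[str] = set()
        for m in modules:
            genes |= m.proteins
    else:
        matching = [m for m in modules if m.module_id == scope]
        if not matching:
            raise ValueError(f"no module with id {scope!r}")
        genes = set(matching[0].proteins)
    net = DiseaseDiseaseNetwork()
    for gene in genes:
        ds = sorted(gene_diseases.get(gene, ()))
        net.diseases.update(ds)
        for i, d1 in enumerate(ds):
            for d2 in ds[i + 1:]:
                e = frozenset((d1, d2))
                net.edges.add(e)
                net.shared_genes.setdefault(e, set()).add(gene)
    return net


def build_bipartite_layer_network(
    module: TopologicalModule, layer_modules: list[LayerModule]
) -> BipartiteLayerNetwork:
    """Protein-to-term bipartite network of one topological module."""
    net = BipartiteLayerNetwork()
    for lm in layer_modules:
        if lm.parent_module_id != module.module_id:
            raise ValueError("layer module from a different parent")
        net.right_nodes.add(lm.term_id)
        for g in lm.genes:
            net.left_nodes.add(g)
            net.edges.add((g, lm.term_id))
    return net


# ---------------------------------------------------------------------------
# I/O


def write_classification_table(classifications: list[ModuleClassification], path) -> None:
    rows = [
        {
            "module_id": c.module_id,
            "mapped_functional": c.mapped_functional,
            "fully_covered": c.fully_covered,
            "mapped_pathway": c.mapped_pathway,
            "mapped_disease": c.mapped_disease,
            "non_trivial": c.non_trivial,
            "significant": c.significant,
        }
        for c in sorted(classifications, key=lambda c: c.module_id)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "module_id", "mapped_functional", "fully_covered", "mapped_pathway",
            "mapped_disease", "non_trivial", "significant",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_bipartite_graphml(net: BipartiteLayerNetwork, path) -> None:
    g = nx.Graph()
    for p in sorted(net.left_nodes):
        g.add_node(p, kind="protein")
    for t in sorted(net.right_nodes):
        g.add_node(t, kind="term")
    g.add_edges_from(sorted(net.edges))
    nx.write_graphml(g, path)


def write_disease_network_graphml(net: DiseaseDiseaseNetwork, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(sorted(net.diseases))
    for e in sorted(net.edges, key=sorted):
        d1, d2 = sorted(e)
        g.add_edge(d1, d2, shared_genes=",".join(sorted(net.shared_genes[e])))
    nx.write_graphml(g, path)
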