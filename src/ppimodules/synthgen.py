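"""Seeded synthetic inputs for every pipeline stage.

The generator emulates the study conditions end to end: a
planted-partition PPI graph (within-module edges with probability
``p_in``, between-module with ``p_out``) plus planted annotations —
one level-3 functional term exactly covering each of a chosen fraction
of modules, noise terms over random gene sets, disease-class plants on
at-least-3-gene subsets of a chosen fraction of modules, pathway plants
mirroring the covering terms, and complexes copying each planted module
for benchmark tests.  All choices are driven by one seed, node
identifiers encode nothing about module labels, and every emitted file
round-trips through the package's own readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ppimodules.detection import ModulePartition, TopologicalModule
from ppimodules.enrichment import AnnotationSet, TermRecord, write_gmt
from ppimodules.layers import DEFAULT_DISEASE_CLASSES, DiseaseClassMap
from ppimodules.netio import ProteinNetwork, write_edgelist


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults match the planted benchmark used throughout the test suite:
    ten modules of eight proteins with dense within-module wiring
    (``p_in`` 0.9) and sparse cross-wiring (``p_out`` 0.01); 70% of
    modules receive a covering functional term, 50% a disease-class
    plant.
    """

    module_sizes: list[int] = field(default_factory=lambda: [8] * 10)
    p_in: float = 0.9
    p_out: float = 0.01
    covering_term_fraction: float = 0.7
    disease_class_fraction: float = 0.5
    n_background_terms: int = 20
    n_disease_classes: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.covering_term_fraction,
                  self.disease_class_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and fractions must be in [0, 1]")
        if sum(self.module_sizes) < 3:
            raise ValueError("at least three nodes required")
        if self.p_in <= self.p_out:
            import logging

            logging.getLogger(__name__).warning(
                "p_in <= p_out: planted structure will not be recoverable"
            )


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset."""

    planted_partition: ModulePartition
    covering_terms: dict[int, str | None]
    planted_disease_modules: dict[int, list[tuple[str, frozenset[str]]]]


def planted_partition_graph(config: SynthConfig) -> tuple[ProteinNetwork, SynthTruth]:
    """Draw a planted-partition graph under the configured conditions.

    Node identifiers are ``P0000``-style labels assigned through a seeded
    permutation, so they carry no information about the planted module.
    """
    rng = np.random.default_rng(config.seed)
    n = sum(config.module_sizes)
    perm = rng.permutation(n)
    names = [f"P{perm[i]:04d}" for i in range(n)]
    membership: list[int] = []
    for mid, size in enumerate(config.module_sizes):
        membership.extend([mid] * size)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            p = config.p_in if membership[i] == membership[j] else config.p_out
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    network = ProteinNetwork(graph=g)
    modules = [
        TopologicalModule(
            module_id=mid,
            proteins=frozenset(
                names[i] for i in range(n) if membership[i] == mid
            ),
        )
        for mid in range(len(config.module_sizes))
    ]
    partition = ModulePartition(
        modules=modules, network_ref=network, method_name="planted"
    )
    truth = SynthTruth(
        planted_partition=partition,
        covering_terms={m.module_id: None for m in modules},
        planted_disease_modules={},
    )
    return network, truth


def _pick_modules(rng: np.random.Generator, module_ids: list[int], fraction: float) -> list[int]:
    """Seeded choice of round(fraction * len(ids)) module ids."""
    k = int(round(fraction * len(module_ids)))
    if k == 0:
        return []
    return sorted(rng.choice(module_ids, size=k, replace=False).tolist())


def plant_annotations(truth: SynthTruth, config: SynthConfig) -> AnnotationSet:
    """Plant covering functional terms and background noise terms.

    A seeded choice of ``covering_term_fraction`` of the planted modules
    each receives one level-3 BP term covering exactly its genes;
    ``n_background_terms`` random gene sets (sizes uniform between 3 and
    twice the mean module size) are added as level-3 noise.  Updates
    ``truth.covering_terms`` in place.
    """
    rng = np.random.default_rng(config.seed + 1)
    modules = truth.planted_partition.modules
    ids = [m.module_id for m in modules]
    by_id = {m.module_id: m for m in modules}
    chosen = _pick_modules(rng, ids, config.covering_term_fraction)
    terms: dict[str, TermRecord] = {}
    for mid in ids:
        truth.covering_terms[mid] = None
    for mid in chosen:
        tid = f"TERM:COVER{mid:03d}"
        terms[tid] = TermRecord(
            name=f"planted covering function {mid}",
            namespace="BP",
            level=3,
            genes=by_id[mid].proteins,
        )
        truth.covering_terms[mid] = tid
    all_genes = sorted(truth.planted_partition.network_ref.proteins)
    mean_size = sum(config.module_sizes) / len(config.module_sizes)
    hi = max(3, int(round(2 * mean_size)))
    for b in range(config.n_background_terms):
        size = int(rng.integers(3, hi + 1))
        size = min(size, len(all_genes))
        genes = frozenset(rng.choice(all_genes, size=size, replace=False).tolist())
        terms[f"TERM:BG{b:03d}"] = TermRecord(
            name=f"background term {b}", namespace="BP", level=3, genes=genes
        )
    return AnnotationSet(terms)


def plant_diseases(
    truth: SynthTruth, config: SynthConfig
) -> tuple[dict[str, set[str]], DiseaseClassMap]:
    """Plant disease-class associations on a fraction of modules.

    Each selected module gets one disease class and an at-least-3-gene
    subset of its proteins carrying a raw disease name unique to that
    (class, module) pair, so per-module disease-disease networks have
    named nodes.  Updates ``truth.planted_disease_modules`` in place.
    """
    rng = np.random.default_rng(config.seed + 2)
    classes = list(DEFAULT_DISEASE_CLASSES[: config.n_disease_classes])
    modules = truth.planted_partition.modules
    ids = [m.module_id for m in modules]
    by_id = {m.module_id: m for m in modules}
    chosen = _pick_modules(rng, ids, config.disease_class_fraction)
    gene_diseases: dict[str, set[str]] = {}
    assignments: dict[str, str] = {}
    truth.planted_disease_modules = {}
    for mid in chosen:
        cls = classes[int(rng.integers(len(classes)))]
        genes = sorted(by_id[mid].proteins)
        size = int(rng.integers(3, len(genes) + 1)) if len(genes) > 3 else 3
        subset = frozenset(rng.choice(genes, size=size, replace=False).tolist())
        disease = f"synthetic {cls} disorder {mid}"
        assignments[disease] = cls
        for g in subset:
            gene_diseases.setdefault(g, set()).add(disease)
        truth.planted_disease_modules.setdefault(mid, []).append((cls, subset))
    class_map = DiseaseClassMap(classes=classes, assignments=assignments)
    return gene_diseases, class_map


def plant_pathways(truth: SynthTruth) -> AnnotationSet:
    """Pathway gene sets mirroring the planted covering terms."""
    terms: dict[str, TermRecord] = {}
    by_id = {m.module_id: m for m in truth.planted_partition.modules}
    for mid, tid in sorted(truth.covering_terms.items()):
        if tid is None:
            continue
        pid = f"PWY:{mid:03d}"
        terms[pid] = TermRecord(
            name=f"planted pathway {mid}",
            namespace="pathway",
            level=None,
            genes=by_id[mid].proteins,
        )
    return AnnotationSet(terms)


def plant_complexes(truth: SynthTruth) -> AnnotationSet:
    """Complexes copying each planted module exactly (benchmark layer)."""
    terms = {
        f"CPX:{m.module_id:03d}": TermRecord(
            name=f"planted complex {m.module_id}",
            namespace="complex",
            level=None,
            genes=m.proteins,
        )
        for m in truth.planted_partition.modules
    }
    return AnnotationSet(terms)


def generate_dataset(config: SynthConfig):
    """Generate the full bundle: network, truth and all annotation layers."""
    network, truth = planted_partition_graph(config)
    functional = plant_annotations(truth, config)
    gene_diseases, class_map = plant_diseases(truth, config)
    pathways = plant_pathways(truth)
    complexes = plant_complexes(truth)
    return network, truth, functional, pathways, gene_diseases, class_map, complexes


def write_dataset(outdir, config: SynthConfig) -> dict[str, str]:
    """Emit the generated dataset in the package's file formats.

    Writes an interaction table (unit confidence, two synthetic source
    databases, direct physical type — so the default filters keep every
    edge), an edge list, gene-term + term-metadata tables, a pathway GMT,
    gene-disease + class-map tables, a complex GMT and the truth JSON.
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, truth, functional, pathways, gene_diseases, class_map, complexes = (
        generate_dataset(config)
    )
    paths = {name: str(outdir / fname) for name, fname in [
        ("interactions", "interactions.tsv"),
        ("edges", "edges.tsv"),
        ("gene_term", "gene_term.tsv"),
        ("term_meta", "term_meta.tsv"),
        ("pathways", "pathways.gmt"),
        ("gene_disease", "gene_disease.tsv"),
        ("class_map", "class_map.tsv"),
        ("complexes", "complexes.gmt"),
        ("truth", "truth.json"),
    ]}
    edge_rows = sorted(tuple(sorted(e)) for e in network.graph.edges)
    pd.DataFrame(
        [
            {
                "protein_a": a,
                "protein_b": b,
                "score": 1.0,
                "sources": "SynthDBA;SynthDBB",
                "interaction_type": "direct physical",
            }
            for a, b in edge_rows
        ]
    ).to_csv(paths["interactions"], sep="\t", index=False)
    write_edgelist(network, paths["edges"])
    gt_rows = sorted(
        (g, tid) for tid, t in functional.terms.items() for g in t.genes
    )
    pd.DataFrame(gt_rows, columns=["gene", "term"]).to_csv(
        paths["gene_term"], sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "term": tid,
                "name": t.name,
                "namespace": t.namespace,
                "level": t.level,
            }
            for tid, t in sorted(functional.terms.items())
        ]
    ).to_csv(paths["term_meta"], sep="\t", index=False)
    write_gmt(pathways, paths["pathways"])
    gd_rows = sorted(
        (g, d, "OMIM") for g, ds in gene_diseases.items() for d in ds
    )
    pd.DataFrame(gd_rows, columns=["gene", "disease_name", "source"]).to_csv(
        paths["gene_disease"], sep="\t", index=False
    )
    pd.DataFrame(
        sorted(class_map.assignments.items()), columns=["disease_name", "class"]
    ).to_csv(paths["class_map"], sep="\t", index=False)
    write_gmt(complexes, paths["complexes"])
    truth_obj = {
        "config": asdict(config),
        "modules": {
            str(m.module_id): sorted(m.proteins)
            for m in truth.planted_partition.modules
        },
        "covering_terms": {str(k): v for k, v in sorted(truth.covering_terms.items())},
        "planted_disease_modules": {
            str(mid): [[cls, sorted(genes)] for cls, genes in plants]
            for mid, plants in sorted(truth.planted_disease_modules.items())
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
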