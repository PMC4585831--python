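"""Detector comparison metrics and the disease-gene benchmark protocol.

Detectors are compared on three axes: Newman modularity Q of their
partition, the *mapping frequency* per annotation layer (fraction of
large topological modules possessing at least one functional, pathway,
disease or complex module), and the *average mapping frequency* (per
large module, the best fraction of its proteins covered by a single
layer module, averaged over large modules).  The benchmark protocol
restricts the interaction set to pairs touching at least one disease
gene before building the network, so every interaction involves disease
genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from ppimodules.detection import (
    DegenerateInputError,
    ModulePartition,
    detect_modules,
    modularity,
)
from ppimodules.enrichment import AnnotationSet, filter_terms_by_level
from ppimodules.enrichment import enrich_module
from ppimodules.integration import ModuleClassification, classify_module, overlap_fraction
from ppimodules.layers import (
    DiseaseClassMap,
    LayerModule,
    call_complex_modules,
    call_disease_modules,
    call_functional_modules,
    call_pathway_modules,
)
from ppimodules.netio import InteractionRecord, ProteinNetwork, build_network

logger = logging.getLogger(__name__)


@dataclass
class AnnotationLayers:
    """Bundle of the annotation inputs for layer calling."""

    functional: AnnotationSet | None = None
    pathways: AnnotationSet | None = None
    gene_diseases: dict[str, set[str]] = field(default_factory=dict)
    class_map: DiseaseClassMap | None = None
    complexes: AnnotationSet | None = None


@dataclass
class PartitionAnalysis:
    """Layer calls and classifications for one partition."""

    partition: ModulePartition
    layer_calls: dict[int, list[LayerModule]]
    fully_covered: dict[int, bool]
    classifications: list[ModuleClassification]
    disease_complex: dict[int, bool]

    def calls_for(self, module_id: int, layer: str) -> list[LayerModule]:
        return [m for m in self.layer_calls.get(module_id, []) if m.layer == layer]


@dataclass
class EvaluationReport:
    """Comparison metrics for one detector."""

    method_name: str
    Q: float
    n_modules_large: int
    mapping_freq: dict[str, float]
    avg_mapping_freq: dict[str, float]
    n_non_trivial: int
    n_significant: int
    fully_covered_freq: float = 0.0
    disease_complex_freq: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.mapping_freq, self.avg_mapping_freq):
            for layer, f in d.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"frequency for {layer} outside [0, 1]: {f}")


def analyze_partition(
    partition: ModulePartition,
    layers_input: AnnotationLayers,
    alpha: float = 0.05,
    level: int | None = 3,
    overlap_threshold: float = 0.5,
    background: set[str] | None = None,
) -> PartitionAnalysis:
    """Run layer calling and classification over a partition's large modules.

    The enrichment background defaults to all annotated proteins of the
    partition's network.  Functional terms are restricted to the given
    GO-slim ``level`` (pass ``None`` to keep all levels).
    """
    functional_ann = layers_input.functional or AnnotationSet()
    if level is not None and len(functional_ann):
        functional_ann = filter_terms_by_level(functional_ann, level)
    pathway_ann = layers_input.pathways or AnnotationSet()
    complex_ann = layers_input.complexes
    if background is None:
        annotated = functional_ann.genes() | pathway_ann.genes()
        background = annotated & partition.network_ref.proteins
    layer_calls: dict[int, list[LayerModule]] = {}
    fully_covered: dict[int, bool] = {}
    classifications: list[ModuleClassification] = []
    disease_complex: dict[int, bool] = {}
    for module in partition.large_modules():
        calls: list[LayerModule] = []
        functional: list[LayerModule] = []
        covered = False
        if len(functional_ann) and background:
            enr = enrich_module(module, functional_ann, background, alpha=alpha)
            annotated_members = module.proteins & functional_ann.genes()
            functional, covered = call_functional_modules(
                module, enr, annotated_proteins=annotated_members
            )
        pathway: list[LayerModule] = []
        if len(pathway_ann) and background:
            enr = enrich_module(module, pathway_ann, background, alpha=alpha)
            pathway = call_pathway_modules(module, enr)
        disease: list[LayerModule] = []
        if layers_input.gene_diseases and layers_input.class_map is not None:
            disease = call_disease_modules(
                module, layers_input.gene_diseases, layers_input.class_map
            )
        complexes: list[LayerModule] = []
        if complex_ann is not None and len(complex_ann):
            complexes = call_complex_modules(module, complex_ann)
        calls = functional + pathway + disease + complexes
        layer_calls[module.module_id] = calls
        fully_covered[module.module_id] = covered
        classifications.append(
            classify_module(
                module, functional, pathway, disease,
                threshold=overlap_threshold, fully_covered=covered,
            )
        )
        disease_complex[module.module_id] = any(
            overlap_fraction(d, c) > overlap_threshold
            for d in disease
            for c in complexes
        )
    return PartitionAnalysis(
        partition=partition,
        layer_calls=layer_calls,
        fully_covered=fully_covered,
        classifications=classifications,
        disease_complex=disease_complex,
    )


def mapping_frequency(
    partition: ModulePartition,
    layer_calls: dict[int, list[LayerModule]],
    layer: str,
    mode: str = "mapped",
    fully_covered: dict[int, bool] | None = None,
) -> float:
    """Fraction of large modules mapped (or fully covered) on a layer.

    ``mode="mapped"`` counts large modules with at least one layer module
    of the given layer; ``mode="fully_covered"`` (functional layer only)
    counts modules whose annotated proteins are all hit by one term and
    requires the ``fully_covered`` flag map.
    """
    large = partition.large_modules()
    if not large:
        raise DegenerateInputError("no large modules to map")
    if mode == "mapped":
        hit = sum(
            1
            for m in large
            if any(lm.layer == layer for lm in layer_calls.get(m.module_id, []))
        )
    elif mode == "fully_covered":
        if fully_covered is None:
            raise ValueError("fully_covered flags required for this mode")
        hit = sum(1 for m in large if fully_covered.get(m.module_id, False))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return hit / len(large)


def average_mapping_frequency(
    partition: ModulePartition,
    layer_calls: dict[int, list[LayerModule]],
    layer: str,
    per_module: str = "max",
) -> float:
    """Mean per-module coverage by the given layer's modules.

    For each large module the coverage is the best (``per_module="max"``,
    default) or mean (``per_module="mean"``) fraction of its proteins
    inside one layer module, zero when unmapped; the result is the mean
    over all large modules.
    """
    large = partition.large_modules()
    if not large:
        raise DegenerateInputError("no large modules to map")
    total = 0.0
    for m in large:
        fracs = [
            len(lm.genes) / len(m.proteins)
            for lm in layer_calls.get(m.module_id, [])
            if lm.layer == layer
        ]
        if not fracs:
            continue
        if per_module == "max":
            total += max(fracs)
        elif per_module == "mean":
            total += sum(fracs) / len(fracs)
        else:
            raise ValueError(f"unknown per_module mode {per_module!r}")
    return total / len(large)


def build_benchmark_network(
    records: list[InteractionRecord], disease_genes: set[str]
) -> ProteinNetwork:
    """Network over the interactions touching at least one disease gene."""
    if not disease_genes:
        raise ValueError("disease gene set must be non-empty")
    kept = [
        r
        for r in records
        if r.protein_a in disease_genes or r.protein_b in disease_genes
    ]
    net = build_network(kept)
    if net.n_edges == 0:
        raise DegenerateInputError("no interaction touches a disease gene")
    return net


def report_from_analysis(
    network: ProteinNetwork, analysis: PartitionAnalysis
) -> EvaluationReport:
    """Build one detector's evaluation report from its analysis."""
    partition = analysis.partition
    large = partition.large_modules()
    mapping = {}
    avg = {}
    for layer in ("functional", "pathway", "disease", "complex"):
        mapping[layer] = mapping_frequency(partition, analysis.layer_calls, layer)
        avg[layer] = average_mapping_frequency(partition, analysis.layer_calls, layer)
    n_large = len(large)
    return EvaluationReport(
        method_name=partition.method_name,
        Q=modularity(network, partition),
        n_modules_large=n_large,
        mapping_freq=mapping,
        avg_mapping_freq=avg,
        n_non_trivial=sum(c.non_trivial for c in analysis.classifications),
        n_significant=sum(c.significant for c in analysis.classifications),
        fully_covered_freq=mapping_frequency(
            partition, analysis.layer_calls, "functional",
            mode="fully_covered", fully_covered=analysis.fully_covered,
        ),
        disease_complex_freq=sum(analysis.disease_complex.values()) / n_large,
    )


def compare_methods(
    network: ProteinNetwork,
    methods: list[dict],
    annotation_layers: AnnotationLayers,
    seed: int = 0,
    alpha: float = 0.05,
    level: int | None = 3,
    overlap_threshold: float = 0.5,
) -> list[EvaluationReport]:
    """Run several detectors through the full mapping pipeline.

    ``methods`` is a list of ``{"name": ..., "params": {...}}`` detector
    configs.  A failing detector is logged and skipped; the others still
    report.  Deterministic given ``seed``.
    """
    if not methods:
        raise ValueError("at least one method required")
    reports: list[EvaluationReport] = []
    for spec in methods:
        name = spec["name"]
        try:
            partition = detect_modules(
                network, method=name, params=spec.get("params"), seed=seed
            )
            analysis = analyze_partition(
                partition, annotation_layers,
                alpha=alpha, level=level, overlap_threshold=overlap_threshold,
            )
            reports.append(report_from_analysis(network, analysis))
        except Exception:
            logger.exception("detector %s failed; continuing", name)
    return reports


def write_reports(reports: list[EvaluationReport], tsv_path, json_path=None) -> None:
    rows = []
    for r in reports:
        row = {
            "method": r.method_name,
            "Q": r.Q,
            "n_modules_large": r.n_modules_large,
            "n_non_trivial": r.n_non_trivial,
            "n_significant": r.n_significant,
            "fully_covered_freq": r.fully_covered_freq,
            "disease_complex_freq": r.disease_complex_freq,
        }
        for layer in ("functional", "pathway", "disease", "complex"):
            row[f"mapped_{layer}"] = r.mapping_freq[layer]
            row[f"avg_mapped_{layer}"] = r.avg_mapping_freq[layer]
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2, sort_keys=True)
            fh.write("\n")
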