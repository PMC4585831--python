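"""One-shot pipeline: build → detect → enrich → call layers → integrate → evaluate.

A :class:`RunConfig` names the input files and the analysis parameters;
:func:`run_pipeline` executes every stage in order, writes all module,
network and report tables into the output directory, and returns the
in-memory analysis.  Outputs are deterministically sorted, so two runs
with the same config and seed produce byte-identical files; a manifest
JSON records inputs, parameters and seed for auditability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ppimodules import __version__
from ppimodules.detection import detect_modules, modularity, write_partition
from ppimodules.enrichment import (
    AnnotationSet,
    apply_obo_levels,
    read_gene_term_table,
    read_gmt,
    term_levels_from_obo,
    write_enrichment_table,
)
from ppimodules.evaluation import (
    AnnotationLayers,
    analyze_partition,
    compare_methods,
    report_from_analysis,
    write_reports,
)
from ppimodules.integration import (
    build_disease_disease_network,
    write_classification_table,
    write_disease_network_graphml,
)
from ppimodules.layers import read_class_map, read_gene_diseases, write_layer_modules
from ppimodules.netio import (
    build_network,
    filter_high_confidence,
    read_edgelist,
    read_interactions,
    write_edgelist,
    write_graphml,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected.

    Defaults follow the method's stated settings: at least two source
    databases, GO-slim level 3, alpha 0.05, MCL inflation 2, RWR restart
    0.4, overlap threshold 0.5 and a minimum module size of 3.
    """

    # inputs
    interactions: str | None = None
    edges: str | None = None
    dialect: dict = field(default_factory=dict)
    gene_term: str | None = None
    term_meta: str | None = None
    obo: str | None = None
    pathways: str | None = None
    gene_disease: str | None = None
    class_map: str | None = None
    complexes: str | None = None
    # filters
    min_score: float = 0.73
    min_sources: int = 2
    required_type: str | None = None
    # detection
    detector: str = "default"
    detector_params: dict = field(default_factory=dict)
    # enrichment / layer calling / integration
    alpha: float = 0.05
    level: int | None = 3
    overlap_threshold: float = 0.5
    # evaluation
    compare: list = field(default_factory=list)  # extra detector configs
    # run control
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("run config must be a YAML mapping")
        return cls.from_dict(data)


def load_annotation_layers(config: RunConfig) -> AnnotationLayers:
    """Read every annotation input named in the config."""
    functional: AnnotationSet | None = None
    if config.gene_term:
        functional = read_gene_term_table(
            config.gene_term, metadata_path=config.term_meta
        )
        if config.obo:
            functional = apply_obo_levels(functional, term_levels_from_obo(config.obo))
    pathways = read_gmt(config.pathways, namespace="pathway") if config.pathways else None
    gene_diseases = (
        read_gene_diseases(config.gene_disease) if config.gene_disease else {}
    )
    class_map = read_class_map(config.class_map) if config.class_map else None
    complexes = (
        read_gmt(config.complexes, namespace="complex") if config.complexes else None
    )
    return AnnotationLayers(
        functional=functional,
        pathways=pathways,
        gene_diseases=gene_diseases,
        class_map=class_map,
        complexes=complexes,
    )


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig):
    """Execute all stages and write artifacts into ``config.outdir``.

    Returns ``(analysis, reports)``.  Raises :class:`PipelineError`
    naming the failed stage; artifacts written before the failure are
    retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # build
    if config.interactions:
        records = _stage("build")(read_interactions, config.interactions, config.dialect)
        records = filter_high_confidence(
            records,
            min_score=config.min_score,
            min_sources=config.min_sources,
            required_type=config.required_type,
        )
        network = build_network(records)
    elif config.edges:
        network = _stage("build")(read_edgelist, config.edges)
    else:
        raise PipelineError("stage 'build' failed: no interactions or edges input")
    logger.info("network: %d proteins, %d edges", network.n_proteins, network.n_edges)
    write_edgelist(network, outdir / "network_edges.tsv")
    write_graphml(network, outdir / "network.graphml")

    # detect
    partition = _stage("detect")(
        detect_modules,
        network,
        method=config.detector,
        params=config.detector_params,
        seed=config.seed,
    )
    logger.info(
        "partition (%s): %d large, %d small modules",
        partition.method_name,
        len(partition.large_modules()),
        len(partition.small_modules()),
    )
    write_partition(partition, outdir / "partition.tsv")

    # enrich + call layers + integrate
    layers_input = _stage("annotations")(load_annotation_layers, config)
    analysis = _stage("call-layers")(
        analyze_partition,
        partition,
        layers_input,
        alpha=config.alpha,
        level=config.level,
        overlap_threshold=config.overlap_threshold,
    )
    all_calls = [lm for calls in analysis.layer_calls.values() for lm in calls]
    logger.info(
        "layer modules: %d; non-trivial: %d; significant: %d",
        len(all_calls),
        sum(c.non_trivial for c in analysis.classifications),
        sum(c.significant for c in analysis.classifications),
    )
    enrich_by_module = {
        mid: [lm.support for lm in calls if lm.support is not None]
        for mid, calls in analysis.layer_calls.items()
    }
    combined = AnnotationSet(
        {
            **(layers_input.functional.terms if layers_input.functional else {}),
            **(layers_input.pathways.terms if layers_input.pathways else {}),
        }
    )
    write_enrichment_table(enrich_by_module, combined, outdir / "enrichment.tsv")
    write_layer_modules(all_calls, outdir / "layer_modules.tsv")
    write_classification_table(analysis.classifications, outdir / "classification.tsv")
    if layers_input.gene_diseases:
        ddn = build_disease_disease_network(
            partition.large_modules(), layers_input.gene_diseases, scope="global"
        )
        write_disease_network_graphml(ddn, outdir / "disease_disease.graphml")

    # evaluate
    reports = [_stage("evaluate")(report_from_analysis, network, analysis)]
    if config.compare:
        reports += _stage("evaluate")(
            compare_methods,
            network,
            list(config.compare),
            layers_input,
            seed=config.seed,
            alpha=config.alpha,
            level=config.level,
            overlap_threshold=config.overlap_threshold,
        )
    write_reports(reports, outdir / "report.tsv", outdir / "report.json")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "network": {"n_proteins": network.n_proteins, "n_edges": network.n_edges},
        "modularity_Q": modularity(network, partition) if network.n_edges else None,
        "n_large_modules": len(partition.large_modules()),
        "n_small_modules": len(partition.small_modules()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return analysis, reports
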