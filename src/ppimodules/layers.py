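"""Call functional, pathway, disease and complex modules.

Each *layer module* is a subset of one topological module's proteins
supported by an annotation layer:

- functional / pathway modules: the hit genes of a significantly
  enriched term, kept when at least three genes are hit;
- disease modules: at least three module genes sharing one of the
  configured disease phenotype classes (a plain counting rule — no
  enrichment test);
- complex modules: the same counting rule keyed on protein-complex
  membership.

A topological module is *fully covered* when a single enriched term hits
all of its annotated proteins (unannotated proteins are ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ppimodules.detection import MIN_MODULE_SIZE, TopologicalModule
from ppimodules.enrichment import AnnotationSet, EnrichmentResult

logger = logging.getLogger(__name__)

LAYERS = ("functional", "pathway", "disease", "complex")

#: Default disease phenotype class vocabulary (15 classes).
DEFAULT_DISEASE_CLASSES = (
    "Neurological",
    "Ophthamological",
    "Cardiovascular",
    "Bone",
    "Dermatological",
    "Endocrine",
    "Metabolic",
    "Cancer",
    "Immunological",
    "Psychiatric",
    "Hematological",
    "Renal",
    "Respiratory",
    "Ear-Nose-Throat",
    "Gastrointestinal",
)


@dataclass(frozen=True)
class LayerModule:
    """A called module on one annotation layer."""

    layer: str
    parent_module_id: int
    genes: frozenset[str]
    term_id: str
    support: EnrichmentResult | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if len(self.genes) < MIN_MODULE_SIZE:
            raise ValueError("layer modules require at least three genes")
        if self.layer == "disease" and self.support is not None:
            raise ValueError("disease modules carry no enrichment support")


@dataclass
class DiseaseClassMap:
    """Disease phenotype classes and the disease-name -> class assignment."""

    classes: list[str] = field(default_factory=lambda: list(DEFAULT_DISEASE_CLASSES))
    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.assignments.values() if c not in self.classes}
        if bad:
            raise ValueError(f"assignment to unknown classes: {sorted(bad)}")

    def class_of(self, disease: str) -> str | None:
        return self.assignments.get(disease)


def call_functional_modules(
    module: TopologicalModule,
    enrichments: list[EnrichmentResult],
    annotated_proteins: set[str] | None = None,
) -> tuple[list[LayerModule], bool]:
    """Functional modules of one topological module, plus full coverage.

    ``enrichments`` must already be significance- and level-filtered.
    Each significant term with at least three hit genes yields one
    functional module.  The parent is *fully covered* when some single
    term's functional module equals the module's annotated proteins
    (``annotated_proteins`` defaults to the union of hit genes across
    terms when not supplied — unannotated proteins never count against
    coverage).
    """
    if annotated_proteins is None:
        annotated = set()
        for r in enrichments:
            annotated |= r.hit_genes
    else:
        annotated = module.proteins & annotated_proteins
    modules = [
        LayerModule(
            layer="functional",
            parent_module_id=module.module_id,
            genes=r.hit_genes,
            term_id=r.term_id,
            support=r,
        )
        for r in enrichments
        if len(r.hit_genes) >= MIN_MODULE_SIZE
    ]
    fully_covered = bool(annotated) and any(
        m.genes == frozenset(annotated) for m in modules
    )
    return modules, fully_covered


def call_pathway_modules(
    module: TopologicalModule, pathway_enrichments: list[EnrichmentResult]
) -> list[LayerModule]:
    """One pathway module per significant pathway with >= 3 hit genes."""
    return [
        LayerModule(
            layer="pathway",
            parent_module_id=module.module_id,
            genes=r.hit_genes,
            term_id=r.term_id,
            support=r,
        )
        for r in pathway_enrichments
        if len(r.hit_genes) >= MIN_MODULE_SIZE
    ]


def call_disease_modules(
    module: TopologicalModule,
    gene_diseases: dict[str, set[str]],
    class_map: DiseaseClassMap,
) -> list[LayerModule]:
    """Disease modules of one topological module.

    For each disease phenotype class, the module genes associated with at
    least one disease of that class form a disease module when more than
    two (i.e. at least three) such genes exist.  A gene may belong to
    several disease modules of the same parent.  Disease names missing
    from the class map are logged and skipped.
    """
    by_class: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for gene in module.proteins:
        for disease in gene_diseases.get(gene, ()):  # noqa: B020
            cls = class_map.class_of(disease)
            if cls is None:
                unmapped.add(disease)
                continue
            by_class.setdefault(cls, set()).add(gene)
    if unmapped:
        logger.info("skipped %d diseases without class assignment", len(unmapped))
    return [
        LayerModule(
            layer="disease",
            parent_module_id=module.module_id,
            genes=frozenset(genes),
            term_id=cls,
        )
        for cls, genes in sorted(by_class.items())
        if len(genes) >= MIN_MODULE_SIZE
    ]


def call_complex_modules(
    module: TopologicalModule, complex_annotations: AnnotationSet
) -> list[LayerModule]:
    """Complex modules: >= 3 module genes in one annotated protein complex."""
    out: list[LayerModule] = []
    for tid in sorted(complex_annotations.terms):
        term = complex_annotations.terms[tid]
        hits = module.proteins & term.genes
        if len(hits) >= MIN_MODULE_SIZE:
            out.append(
                LayerModule(
                    layer="complex",
                    parent_module_id=module.module_id,
                    genes=frozenset(hits),
                    term_id=tid,
                )
            )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_gene_diseases(path) -> dict[str, set[str]]:
    """Read (gene, disease_name[, source]) TSV into gene -> disease names."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for g, d in zip(table.iloc[:, 0], table.iloc[:, 1]):
        if pd.isna(g) or pd.isna(d):
            continue
        out.setdefault(str(g), set()).add(str(d))
    return out


def read_class_map(path, classes: list[str] | None = None) -> DiseaseClassMap:
    """Read a (disease_name, class) TSV into a :class:`DiseaseClassMap`."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    assignments = {
        str(d): str(c)
        for d, c in zip(table.iloc[:, 0], table.iloc[:, 1])
        if not (pd.isna(d) or pd.isna(c))
    }
    if classes is None:
        classes = sorted(set(assignments.values()) | set(DEFAULT_DISEASE_CLASSES))
    return DiseaseClassMap(classes=classes, assignments=assignments)


def read_layer_modules(path) -> list[LayerModule]:
    """Read a layer-module TSV back (enrichment support is not restored)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out: list[LayerModule] = []
    for row in table.itertuples(index=False):
        out.append(
            LayerModule(
                layer=str(row.layer),
                parent_module_id=int(row.parent_module_id),
                genes=frozenset(str(row.genes).split(",")),
                term_id=str(row.term_or_class),
            )
        )
    return out


def write_layer_modules(layer_modules: list[LayerModule], path) -> None:
    """Layer-module TSV (layer, parent, term/class, size, genes, p, p_adj)."""
    rows = []
    for lm in sorted(
        layer_modules, key=lambda m: (m.parent_module_id, m.layer, m.term_id)
    ):
        rows.append(
            {
                "layer": lm.layer,
                "parent_module_id": lm.parent_module_id,
                "term_or_class": lm.term_id,
                "n_genes": len(lm.genes),
                "genes": ",".join(sorted(lm.genes)),
                "p_value": lm.support.p_value if lm.support else "",
                "p_adjusted": lm.support.p_adjusted if lm.support else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "layer", "parent_module_id", "term_or_class", "n_genes", "genes",
            "p_value", "p_adjusted",
        ],
    ).to_csv(path, sep="\t", index=False)
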