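"""Hypergeometric over-representation testing with BH-FDR correction.

A module's proteins are tested against term gene sets (GO slim terms,
pathways, diseases, complexes).  For a module with ``n`` annotated
proteins drawn from a background of ``N`` genes, a term annotating ``K``
background genes and hitting ``k`` module genes gets the upper-tail
probability P(X >= k) under the hypergeometric distribution.  P-values
are corrected per module and per namespace with the Benjamini-Hochberg
step-up procedure, and only terms with adjusted P below ``alpha``
(default 0.05) are reported.

GO-slim style term *levels* (1 = namespace root) can be supplied in the
annotation metadata or computed from an OBO ontology as one plus the
length of the shortest ``is_a`` path to the namespace root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ppimodules.detection import DegenerateInputError, TopologicalModule

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "CC", "MF", "pathway", "disease", "complex")


@dataclass(frozen=True)
class TermRecord:
    """One annotation term: name, namespace, optional level, gene set."""

    name: str
    namespace: str
    level: int | None
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("term gene set must be non-empty")
        if self.level is not None and self.level < 1:
            raise ValueError("term level must be >= 1")


@dataclass
class AnnotationSet:
    """Mapping from term identifiers to :class:`TermRecord`."""

    terms: dict[str, TermRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> set[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out

    def subset_namespace(self, namespace: str) -> "AnnotationSet":
        return AnnotationSet(
            {tid: t for tid, t in self.terms.items() if t.namespace == namespace}
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test outcome for one term against one module."""

    term_id: str
    k: int  # module genes annotated to the term
    K: int  # background genes annotated to the term
    n: int  # annotated module genes
    N: int  # background size
    p_value: float
    p_adjusted: float
    hit_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.n <= self.N and self.K <= self.N):
            raise ValueError("inconsistent contingency counts")
        if self.p_adjusted < self.p_value - 1e-15:
            raise ValueError("adjusted p-value below raw p-value")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` hits among ``n`` draws from a population of ``N`` with ``K``
    successes.  Computed through the survival function for numerical
    stability.
    """
    if N < 1 or not (0 <= k <= min(K, n)) or K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return adj.tolist()


def filter_terms_by_level(annotations: AnnotationSet, level: int) -> AnnotationSet:
    """Keep exactly the terms whose level equals ``level``.

    Terms without level metadata are dropped with a logged warning.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    kept: dict[str, TermRecord] = {}
    n_unlevelled = 0
    for tid, t in annotations.terms.items():
        if t.level is None:
            n_unlevelled += 1
        elif t.level == level:
            kept[tid] = t
    if n_unlevelled:
        logger.warning("dropped %d terms without level metadata", n_unlevelled)
    if not kept:
        logger.warning("no terms at level %d", level)
    return AnnotationSet(kept)


def enrich_module(
    module: TopologicalModule,
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Significant term enrichments of one module.

    Every term with at least one hit in the module is tested; BH
    correction is applied across all tested terms of one namespace
    within this module.  Returns results with adjusted P below ``alpha``,
    sorted by (adjusted P, term id).
    """
    if not background:
        raise DegenerateInputError("empty background set")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    module_bg = module.proteins & background
    n, N = len(module_bg), len(background)
    results: list[EnrichmentResult] = []
    by_namespace: dict[str, list[tuple[str, TermRecord, frozenset[str]]]] = {}
    for tid, term in annotations.terms.items():
        hits = frozenset(module_bg & term.genes)
        if hits:
            by_namespace.setdefault(term.namespace, []).append((tid, term, hits))
    for _, tested in sorted(by_namespace.items()):
        raw = [
            hypergeom_pvalue(len(hits), len(term.genes & background), n, N)
            for _, term, hits in tested
        ]
        adjusted = bh_adjust(raw)
        for (tid, term, hits), p, q in zip(tested, raw, adjusted):
            if q < alpha:
                results.append(
                    EnrichmentResult(
                        term_id=tid,
                        k=len(hits),
                        K=len(term.genes & background),
                        n=n,
                        N=N,
                        p_value=p,
                        p_adjusted=q,
                        hit_genes=hits,
                    )
                )
    results.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return results


# ---------------------------------------------------------------------------
# annotation I/O


def read_gmt(path, namespace: str = "pathway") -> AnnotationSet:
    """Read term gene sets from a GMT file (term, description, genes...)."""
    terms: dict[str, TermRecord] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            tid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if genes:
                terms[tid] = TermRecord(
                    name=name, namespace=namespace, level=None, genes=frozenset(genes)
                )
    return AnnotationSet(terms)


def write_gmt(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(annotations.terms):
            t = annotations.terms[tid]
            fh.write("\t".join([tid, t.name, *sorted(t.genes)]) + "\n")


def read_gene_term_table(path, metadata_path=None, namespace: str = "BP") -> AnnotationSet:
    """Read a two-column (gene, term) TSV with optional term-metadata TSV.

    The metadata table carries columns ``term``, ``name``, ``namespace``
    and ``level``; terms missing from it fall back to the default
    namespace with no level.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, term_col = table.columns[0], table.columns[1]
    gene_sets: dict[str, set[str]] = {}
    for g, t in zip(table[gene_col], table[term_col]):
        if pd.isna(g) or pd.isna(t):
            continue
        gene_sets.setdefault(str(t), set()).add(str(g))
    meta: dict[str, tuple[str, str, int | None]] = {}
    if metadata_path is not None:
        md = pd.read_csv(metadata_path, sep="\t", dtype=str)
        for row in md.itertuples(index=False):
            level = None if pd.isna(row.level) else int(float(row.level))
            meta[str(row.term)] = (str(row.name), str(row.namespace), level)
    terms: dict[str, TermRecord] = {}
    for tid, genes in gene_sets.items():
        name, ns, level = meta.get(tid, (tid, namespace, None))
        terms[tid] = TermRecord(name=name, namespace=ns, level=level, genes=frozenset(genes))
    return AnnotationSet(terms)


def term_levels_from_obo(path) -> dict[str, int]:
    """Compute term levels from an OBO ontology.

    The level of a term is one plus the length of the shortest ``is_a``
    path to the root of its namespace (roots have level 1).
    """
    onto = obonet.read_obo(path)
    isa = nx.DiGraph()
    isa.add_nodes_from(onto.nodes)
    for child, parent, key in onto.edges(keys=True):
        if key == "is_a":
            isa.add_edge(child, parent)
    roots = {n for n in isa.nodes if isa.out_degree(n) == 0}
    levels: dict[str, int] = {}
    for root in roots:
        for node, dist in nx.shortest_path_length(isa.reverse(copy=False), root).items():
            lvl = dist + 1
            if node not in levels or lvl < levels[node]:
                levels[node] = lvl
    return levels


def apply_obo_levels(annotations: AnnotationSet, levels: dict[str, int]) -> AnnotationSet:
    """Attach ontology-derived levels to an annotation set."""
    terms = {
        tid: TermRecord(t.name, t.namespace, levels.get(tid, t.level), t.genes)
        for tid, t in annotations.terms.items()
    }
    return AnnotationSet(terms)


def write_enrichment_table(
    results: dict[int, list[EnrichmentResult]], annotations: AnnotationSet, path
) -> None:
    """Per-module enrichment TSV, sorted for stable output."""
    rows = []
    for mid in sorted(results):
        for r in results[mid]:
            term = annotations.terms.get(r.term_id)
            rows.append(
                {
                    "module_id": mid,
                    "term_id": r.term_id,
                    "name": term.name if term else r.term_id,
                    "namespace": term.namespace if term else "",
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "N": r.N,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                    "hit_genes": ",".join(sorted(r.hit_genes)),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "module_id", "term_id", "name", "namespace", "k", "K", "n", "N",
            "p_value", "p_adjusted", "hit_genes",
        ],
    ).to_csv(path, sep="\t", index=False)
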