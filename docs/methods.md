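# Methods

## The mapping procedure

The package treats a PPI network as the base layer and annotation
layers (GO terms, pathways, disease–gene associations, protein
complexes) as overlays. The analysis is a fixed composition:

1. filter interactions (≥ 2 reporting databases, confidence ≥ cutoff,
   optional interaction-type match) and build an undirected simple
   graph;
2. partition the graph into topological modules; modules with < 3
   proteins are retained in outputs but excluded from all layer
   calling;
3. per large module, test annotation terms by the one-sided
   hypergeometric test and correct with Benjamini–Hochberg within one
   module and one namespace; significant terms (adjusted *P* < α,
   default 0.05) with ≥ 3 hit genes yield functional/pathway modules;
4. per large module and disease phenotype class, ≥ 3 genes associated
   with diseases of that class yield a disease module (a counting rule,
   no test); the same rule keyed on complex membership yields complex
   modules;
5. classify: *non-trivial* iff some disease module overlaps some
   functional module on strictly more than half of the **disease
   module's** proteins; *significant* likewise against pathway modules;
6. evaluate detectors by modularity Q, mapping frequency (fraction of
   large modules with ≥ 1 layer module) and average mapping frequency
   (mean over large modules of the best per-term coverage fraction).

## Detectors

**Default.** Multi-level greedy modularity maximization
(Louvain-style local moving and aggregation, seeded and deterministic),
followed by a refinement pass that visits nodes in sorted order and
accepts single-node moves that strictly increase Q (ties to the lowest
community index). We chose multi-level maximization over single-pass
CNM-style agglomeration after observing that pairwise agglomeration
systematically merges small planted modules at realistic densities
(it recovered 10×8-node planted modules exactly in only a quarter of
runs, versus all runs for the multi-level scheme). The detector
interface is pluggable (`read_partition` injects externally computed
clusterings), so any other community detector's output can be dropped
in.

**MCL.** Expansion (matrix squaring) alternating with inflation
(entrywise power r, default 2, then column renormalization) on the
column-stochastic adjacency matrix with unit self-loops. Entries below
1e−8 are pruned; iteration stops when the largest entrywise change
falls below that threshold or after 100 iterations (logged warning).
Clusters are read from attractor rows (positive self-mass); a node
claimed by several attractors joins the lowest-numbered cluster. The
dense-matrix implementation is intentional: the package targets
module-level analyses of networks with 10²–10⁴ nodes.

**RWR.** For each seed s, the affinity vector of
p ← (1−r)·W·p + r·e_s (W column-normalized adjacency, restart r
default 0.4) is iterated to an L1 tolerance of 1e−10. Clusters are the
argmax-affinity assignment per node, ties to the lexicographically
smaller seed; nodes unreachable from every seed land in a designated
unassigned module. How walk affinities become disjoint clusters, and
how seeds are chosen, are genuinely open choices; we use argmax
extraction, and default seeds are the loaded disease genes or, absent
those, a seeded random sample of round(√n) nodes.

## Statistical choices

- Hypergeometric tail P(X ≥ k) is computed through the survival
  function (`scipy.stats.hypergeom.sf`); BH through
  `statsmodels.stats.multitest.multipletests`. Both are cross-checked
  in the test suite against independent oracles (exhaustive draw
  enumeration; hand-written step-up).
- The enrichment background defaults to all annotated proteins of the
  analysed network, not the whole genome; it is configurable. A
  whole-genome background would shrink p-values for every term alike
  and mostly inflate significance.
- Term *level* is 1 + length of the shortest `is_a` path to the
  namespace root (roots have level 1), computed from an OBO file with
  `obonet`, or taken from a precomputed `level` column. Level-3
  filtering is applied to functional terms only.
- Result ordering and all tie-breaks are lexicographic after the
  primary sort key, so outputs are byte-stable across runs.

## Rule boundaries

"More than two proteins" is read as ≥ 3, matching the ≥ 3-protein
floor used for topological and functional modules. "Over half" is
strict: an overlap of exactly 0.5 never classifies a module as
non-trivial or significant. The overlap denominator is the disease
module's size (configurable to the minimum of the two sizes). Full
coverage ignores proteins with no annotation at all, and holds exactly
when some single enriched term's functional module equals the module's
annotated proteins (a union-of-terms reading is deliberately not the
default).

## Synthetic data

The generator plants a partition (default ten modules of eight
proteins) and draws within-module edges with probability p_in = 0.9
and between-module edges with p_out = 0.01 — dense modules with sparse
cross-talk, the regime the mapping method assumes. Node labels are
assigned through a seeded permutation so identifiers carry no module
information. Annotation plants are exact by construction: a covering
term annotates precisely its module's genes (70% of modules by
default), a disease plant marks a ≥ 3-gene subset with a class-unique
disease name (50% of modules), pathways mirror the covering terms and
complexes copy every module. Background noise terms (default 20, sizes
uniform between 3 and twice the mean module size — an arbitrary,
documented choice) exercise the multiple-testing path.

Because plants are exact covers, a perfect detector must recover the
planted fractions exactly: fully-covered frequency = covering-term
fraction, disease mapping frequency = disease-class fraction, and the
non-trivial modules are exactly those carrying both plants. The tests
and the acceptance script verify precisely this. What passing does
**not** show: real PPI networks are scale-free with hub proteins,
annotation is incomplete and biased toward well-studied genes, GO terms
overlap hierarchically rather than partitioning genes, and real
disease–gene associations are far noisier than exact subsets. The
synthetic conditions validate the machinery and its rule boundaries,
not biological discovery performance.

## Problem sizes and numerics

The test suite and the acceptance script run on 80-node planted graphs
(ten modules of eight), 20 seeds for recovery statistics, and random
graphs up to 50 nodes for the modularity oracle; these sizes make every
check exact or near-exact while keeping the full suite in the
low-seconds range. Degenerate inputs are errors, not silent defaults:
modularity on an edgeless graph, enrichment against an empty
background, mapping frequencies without large modules, MCL on an empty
network. MCL non-convergence returns the current clustering with a
warning rather than failing.

## Known limitations

- The default confidence cutoff (0.73) is a configurable stand-in for
  a "high-confidence" score threshold that depends on the upstream
  scoring system; the ≥ 2-database rule is the hard filter.
- Pathway enrichment uses the same plain hypergeometric test as GO
  terms; EASE-style conservative variants are not implemented.
- Detectors treat the graph as unweighted; confidence scores filter
  interactions but do not weight edges.
- Overlapping community detection is out of scope; every detector
  returns disjoint modules.
- Disease modules are called by class membership counting only; an
  enrichment-based variant is a possible extension but is deliberately
  not the default.
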