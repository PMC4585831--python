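# ppimodules

Integrative mapping of protein interaction, function and disease
networks.

Protein–protein interaction (PPI) networks, functional annotation
(Gene Ontology terms, pathways) and disease–gene associations are
usually analysed separately. `ppimodules` implements a multi-network
mapping method that ties the three levels together, for systems
biologists who want module-level, cross-layer annotations of a PPI
network:

1. **Topological modules** — a high-confidence PPI network is built
   from scored interaction tables (an interaction is kept when it is
   reported by ≥ 2 source databases, reaches a confidence cutoff, and
   optionally is a direct physical interaction), then partitioned with
   a pluggable graph-clustering detector. Partitions are scored by
   Newman modularity

   *Q* = Σ<sub>c</sub> [ *L*<sub>c</sub>/*m* − (*d*<sub>c</sub>/2*m*)² ],

   with *m* the edge count, *L*<sub>c</sub> the intra-module edges and
   *d*<sub>c</sub> the summed degree of module *c*. Only modules with
   ≥ 3 proteins enter downstream analysis.
2. **Functional and pathway modules** — each topological module is
   tested for term over-representation with the one-sided
   hypergeometric test, corrected per module and namespace by
   Benjamini–Hochberg FDR (significance at adjusted *P* < 0.05; GO-slim
   terms restricted to level 3). The ≥ 3 hit genes of a significant
   term form a functional (or pathway) module; a topological module is
   *fully covered* when one term hits all of its annotated proteins.
3. **Disease modules** — ≥ 3 module genes sharing one of 15 disease
   phenotype classes (Neurological, Cardiovascular, Bone, …) form a
   disease module; disease–disease networks link diseases sharing a
   disease gene.
4. **Integration** — a topological module is **non-trivial** when a
   disease module overlaps a functional module on more than half of the
   disease module's proteins, and **significant** when the same holds
   with a pathway module.
5. **Evaluation** — detectors (default multi-level modularity
   clustering, Markov Clustering with inflation r = 2, random walk with
   restart r = 0.4) are compared by modularity, per-layer mapping
   frequency and average mapping frequency, optionally on a benchmark
   network restricted to interactions touching disease genes.

A seeded synthetic-data generator (planted-partition graphs with
planted covering terms, disease classes, pathways and complexes) makes
every stage testable without any database downloads.

## Worked example

Generate a synthetic dataset (10 planted modules of 8 proteins, 70% of
modules with a covering GO term, 50% with a planted disease class) and
run the full pipeline, comparing the default detector with MCL and a
random walker:

```sh
ppimodules synth --out data --seed 7
cat > run.yaml <<EOF
interactions: data/interactions.tsv
gene_term: data/gene_term.tsv
term_meta: data/term_meta.tsv
pathways: data/pathways.gmt
gene_disease: data/gene_disease.tsv
class_map: data/class_map.tsv
complexes: data/complexes.gmt
seed: 7
outdir: results
compare:
  - {name: mcl}
  - {name: rwr}
EOF
ppimodules pipeline --config run.yaml
```

which prints

```
10 large modules; non-trivial: 5; significant: 5; outputs in results
```

and writes `results/report.tsv` containing (selected columns):

```
 method        Q  n_modules_large  fully_covered_freq  mapped_disease  n_non_trivial
default 0.815156               10               0.700           0.500              5
    mcl 0.815156               10               0.700           0.500              5
    rwr 0.514260                8               0.125           0.375              3
```

The default detector and MCL both recover the ten planted modules
(Q ≈ 0.82 for this draw); the fully-covered frequency 0.7 and disease
mapping frequency 0.5 recover the planted fractions exactly, and the
five non-trivial modules are exactly those carrying both a covering
term and a disease plant. The random walker, seeded with √n random
nodes, splits the network more coarsely and maps fewer modules.

Every stage is also available as its own subcommand (`build-net`,
`detect`, `enrich`, `call-layers`, `integrate`, `evaluate`), each
runnable on the files a previous stage wrote, and as plain library
functions (`ppimodules.detect_modules`, `ppimodules.enrich_module`,
…).

## Layout

- `src/ppimodules/netio.py` — interaction tables, evidence filters, PPI graph I/O
- `src/ppimodules/detection.py` — detectors (default, MCL, RWR), modularity
- `src/ppimodules/enrichment.py` — hypergeometric tests, BH-FDR, term levels, OBO
- `src/ppimodules/layers.py` — functional / pathway / disease / complex module calling
- `src/ppimodules/integration.py` — overlap classification, cross-layer networks
- `src/ppimodules/evaluation.py` — mapping frequencies, benchmark, method comparison
- `src/ppimodules/synthgen.py` — seeded planted-partition data generator
- `src/ppimodules/pipeline.py`, `cli.py` — run config, one-shot pipeline, CLI

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
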