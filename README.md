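# astrodiverge

Cross-species comparative transcriptomics for human and mouse astrocytes —
and, more generally, for any pair of species linked by a one-to-one ortholog
table.

Bulk RNA-seq of purified astrocytes shows that human and mouse astrocytes
share most of their expression program but diverge sharply in defense
response and metabolism genes, and respond differently to hypoxia and
inflammatory stimuli. Quantifying that conservation and divergence poses a
chain of statistical problems that this package implements as a tested,
reusable pipeline:

- **Percentile-rank species divergence.** Absolute expression (RPKM) is not
  comparable across species, so each gene is reduced to its within-sample
  percentile rank `(r − 1)/(G − 1) ∈ [0, 1]` (average rank on ties). After
  excluding genes whose maximal rank across all samples is below 1/3, each
  ortholog pair is tested with Welch's unequal-variance t-test on per-sample
  ranks, Benjamini–Hochberg adjusted; a gene is species-divergent when
  FDR < 0.05 *and* |mean rank difference| > 0.4. The signed rank difference
  ("hmDiff", human minus mouse) is also correlated across datasets, e.g.
  acutely purified vs xenografted astrocytes.
- **Treatment differential expression.** A negative-binomial Wald test
  (median-of-ratios size factors; moment dispersion `Var = μ + φμ²` shrunk
  50/50 to the genewise mean; t reference with Satterthwaite-style effective
  df) with the directional DEG filter FDR < 0.05, fold change > 1.5, mean
  RPKM of control *or* treated group > 1.
- **Set statistics.** Hypergeometric overlap enrichment (representation
  factor `k/(n₁n₂/N)` and exact upper-tail p), two-sided Fisher/χ²
  directional concordance between up/down DEG list pairs (χ² without
  continuity correction at ≥ 1000 genes, Fisher otherwise), Bonferroni
  family correction, and core-signature intersection across comparisons.
- **Co-expression modules.** A compact WGCNA-style stage: > 20 % non-zero
  gene filter, log2(x + 0.001), within-replicate-pair centering, biweight
  midcorrelation (c = 9), signed adjacency |bicor|^β at soft power 18 with a
  scale-free-topology r² diagnostic, topological overlap, average-linkage
  tree cut with a 50-gene module floor, module eigengenes and module–trait
  correlation.
- **Xenograft read deconvolution.** Reads from graft/host mixtures are
  assigned to species by exact k-mer scoring against a combined reference
  whose records are tagged `chr|` (human) and `m.chr|` (mouse), with seeded
  random tie-breaking, count splitting that conserves reads exactly, and
  truth-based false-assignment benchmarking.
- **Synthetic data with planted truth.** NB count matrices with planted
  species-divergent genes, paired control/treated designs with a
  configurable conserved response fraction, divergent ortholog transcript
  pairs and error-bearing reads — everything downstream is validated by
  recovering what was planted.

## Worked example

Run the end-to-end synthetic pipeline (simulate → RPKM → percentile ranks →
species test → treatment DE per species → cross-species overlap):

```python
from astrodiverge import pipeline
pipeline.run_pipeline({"seed": 1}, "runs/demo")
print(pipeline.report("runs/demo"))
```

```
astrodiverge run report — seed 1

orthologs tested for species divergence: 1604
  higher in human: 85
  higher in mouse: 90

human treatment DE: 2000 genes tested, 77 up, 78 down
mouse treatment DE: 2000 genes tested, 77 up, 78 down
cross-species up overlap: 50 of 77 human genes (64.9%)
cross-species down overlap: 48 of 78 human genes (61.5%)
```

Reading the numbers: of 2000 simulated orthologs, 1604 pass the expression
filter; the 85 + 90 divergent calls recover the planted 10 % divergent
fraction (split between the two directions) that survives the filter. Each
species' treatment comparison finds ~150 DEGs, and roughly 60 % of the human
response is shared with mouse — the planted design makes half the responsive
genes conserved, and the union-based estimator
`treatment_de.estimate_conserved_fraction` converts these overlap counts
back into an estimate of that fraction.

The same stages are exposed on the command line (`astrodiverge --help`):
`simulate`, `quantify`, `species-de`, `treat-de`, `setstats`, `coexpr`,
`xenosplit`, `run`, `report`.

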