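# Methods

This note documents the statistical procedures, the parameters that matter,
the synthetic-data model behind the test suite, and the numerical and design
choices that were genuinely open.

## Percentile-rank species comparison

Expression levels are not directly comparable across species: library
composition, annotation completeness and probe efficiency all differ. The
pipeline therefore reduces each gene to its within-sample percentile rank.
With `G` genes per sample, the average rank `r ∈ {1..G}` maps to
`(r − 1)/(G − 1)`, so the least expressed gene sits at 0, the most expressed
at 1, and a fully tied sample at 0.5. This convention makes the published
thresholds interpretable on [0, 1]: the expression filter keeps ortholog
pairs whose maximal rank across all samples of both species is ≥ 1/3 ("top
two-thirds"), and divergence calls require a mean-rank difference > 0.4.
Ranks are invariant to any strictly monotone within-sample transform, so
RPKM vs depth-normalized counts only matters through the gene-length factor.

Per ortholog pair, per-sample ranks are compared with Welch's t-test
(unequal variances, Welch–Satterthwaite df), two-sided, followed by
Benjamini–Hochberg FDR (or Bonferroni, used for the host-vs-naïve variant of
the comparison) computed over exactly the post-filter ortholog set — the
filter precedes testing. Degenerate rows (zero variance in both species) get
p = 1 at equal means; at unequal means they are flagged and assigned p = 0.
Thresholds are strict inequalities (FDR < 0.05, |Δrank| > 0.4).

The signed rank difference (human minus mouse, "hmDiff") is the unit for
cross-dataset comparisons: the Pearson correlation of hmDiff vectors between
two datasets (e.g. acutely purified vs xenografted astrocytes) measures
whether species differences persist across conditions.

## Quantification

RPKM is `count / (length_bp/10³) / (library/10⁶)` with the library size
taken as the column sum of the count matrix — the only self-contained
choice when aligner-reported mapped-read totals are unavailable. Annotation
must cover every gene; a missing length is an error rather than a silent
drop. Row z-scores use the sample standard deviation (ddof = 1); constant
rows are flagged and set to 0. The two-correlation test is Fisher's r-to-z:
`(atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))` against a standard normal,
two-sided. Reference-strain normalization divides each sample by the
reference-group mean per gene, dropping (and reporting) genes with zero
reference mean; cluster-mean fold changes use a configurable pseudocount
(default 0.01) before log2.

## Treatment differential expression

The two-group test is a compact negative-binomial Wald test:

1. **Size factors** by median-of-ratios against the geometric-mean reference
   over genes with all-positive counts.
2. **Dispersion** `φ` in `Var = μ + φμ²` by method of moments on normalized
   counts (pooled within-group variance), floored at 1e−8 and shrunk 50/50
   toward the genewise mean dispersion. The single-floor-plus-shrinkage
   scheme trades per-gene adaptivity for stability at 4 samples per group.
3. **Wald statistic** on `log2((μ̂_t + 0.5)/(μ̂_c + 0.5))` with a model-based
   delta-method standard error, `Var(μ̂) = (μ̂ + φμ̂²)/n` per group.
4. **Reference distribution**: t with effective df `4(n₁ + n₂ − 2)`. The
   50/50 dispersion shrinkage mixes a ~(n₁+n₂−2)-df genewise estimate with a
   near-noiseless trend component; a Satterthwaite-style argument gives
   roughly four times the residual df. A plain normal reference is
   measurably too light in the far tail at n = 4 + 4 (over a third of
   complete-null simulations produced a spurious BH discovery), which the t
   reference removes while keeping the central type-I rate near nominal
   (~0.049 pooled over 50 null simulations).
5. **BH adjustment** over all testable genes (genes all-zero in both groups
   are excluded as untestable).

The test is unpaired: replicate-pair labels are used by the co-expression
stage but not by the DE design. DEG calls apply the three-way filter
FDR < 0.05, linear fold change > 1.5 in the relevant direction, and mean
RPKM > 1 in the control *or* treated group (a disjunction). Alternate
threshold sets (fold change 4 with average RPKM, fold change 2 with maximum
RPKM, FDR 0.1 with RPKM 1.5) are expressible through the same function's
arguments.

Cross-species overlap maps mouse DEG ids through the ortholog table and
reports, per direction, `100·|overlap|/|human set|` — the share of the human
response conserved in mouse. `estimate_conserved_fraction` pools both
directions and estimates the planted conserved fraction as
`|A∩B| / |A∪B|`; imperfect per-species recall makes it mildly conservative
(simulations at the default effect size recover a planted 0.5 to within
0.04–0.06).

## Set statistics

Overlap enrichment on an explicit background of size `N` (never defaulted —
an implicit background makes enrichment p-values irreproducible): expected
overlap `n₁n₂/N`, representation factor `k/expected`, exact hypergeometric
upper tail `P(X ≥ k)`. Directional concordance crosses two up/down DEG list
pairs into the 2×2 table (up/up, up/down, down/up, down/down), tested
two-sided by Fisher's exact test below 1000 genes and by χ² (no continuity
correction) at ≥ 1000; if any expected cell is below 5 the χ² falls back to
Fisher and records the fallback — a validity guard on top of the size rule.
Bonferroni multiplies by the declared comparison family size. The core
signature is the straight intersection of all `up` (resp. `down`) sets;
direction-discordant genes drop out by construction.

## Co-expression modules

The network stage merges the two species' matrices through one-to-one
orthologs, keeps genes with > 20 % non-zero values, applies log2(x + 0.001),
and removes between-replicate-pair variation by subtracting each pair's mean
per gene — the closed-form solution of the random-intercept model
`expr ~ (1 | replicate)` in the balanced case. This keeps within-pair
treatment contrasts while removing basal species and batch differences.

Similarity is the biweight midcorrelation with tuning constant 9 (weights
`(1 − u²)² · 1(|u| < 1)`, `u = (x − med)/(9·MAD)`); genes with zero MAD but
non-constant values fall back to the Pearson transform and are flagged.
Adjacency is `|bicor|^β` with default soft power 18; the scale-free fit r²
(log10 p(k) vs log10 k over ≥ 10 connectivity bins) is reported as the
power diagnostic, with 0.8 the conventional adequacy target. The topological
overlap matrix is `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
with unit diagonal.

**Tree cut.** 1 − TOM is clustered by average linkage. A fixed-height cut is
supported, but at β = 18 all within-module merge heights compress into a
narrow band just below 1 (an adjacency of 0.7¹⁸ ≈ 1.6e−3 puts within-module
TOM dissimilarity near 0.998), so no single fixed height is robust across
correlation strengths. The default is therefore an adaptive cut: sweep every
candidate cut height and keep the one producing the most clusters at or
above the 50-gene module floor, breaking ties toward the higher cut; then
prune genes whose module membership (|kME|, the correlation with their
module's eigengene) is below 0.5 into the unassigned bin. This replaces the
dynamic tree cut of full WGCNA with a one-objective approximation that
recovers planted correlation blocks essentially perfectly (ARI ≥ 0.99 over
10 seeds on a 4-block, 600-gene, 48-sample design) while remaining a pure
function of the dendrogram plus one membership threshold. Module eigengenes
are the unit-norm first principal component of the module's standardized
expression, sign-anchored to correlate positively with the module's average
expression; module–trait association is Pearson r with its two-sided p.

## Synthetic data

The generators define the conditions under which every downstream stage is
validated:

- **Counts** are negative binomial, `Var = μ + φμ²`, with a single φ = 0.1
  shared across genes — typical biological-replicate overdispersion for
  bulk RNA-seq. Per-gene baseline log2 abundances are Normal(3, 2²);
  per-sample library sizes are drawn uniformly from 0.8–1.2 million and
  enter through μ (no post-hoc thinning), keeping the NB form exact.
- **Species divergence** marks `round(frac·n)` genes (default 10 %), split
  evenly between a human-up and mouse-up half, and applies the log2 shift
  symmetrically (+shift/2 in one species, −shift/2 in the other). A
  one-sided shift cannot move a top-ranked gene's percentile, so the
  symmetric contrast is what makes rank-based recovery well defined. The
  default total shift of 6 log2 units moves the median planted gene's rank
  by ≈ 0.7, comfortably past the 0.4 calling threshold; at these settings
  the divergence caller achieves precision 1.0 and recall ≈ 0.9 at 6
  samples per species (recall is bounded by genes planted near the rank
  extremes, which cannot move far enough).
- **Treatment responses** mark `round(frac·n)` responsive genes (default
  10 %) with a ±2 log2-unit fold change in treated samples; a configurable
  conserved fraction responds in both species, the remainder split evenly
  between human-only and mouse-only responders, and up/down directions are
  split evenly within every class. Four replicates per group mirror a
  typical treatment design.
- **Sequences**: ortholog transcript pairs differ by independent per-base
  substitution (uniform over the three alternatives) at a configurable
  divergence; reads have uniform start positions and per-base substitution
  errors, with species and transcript of origin encoded in the read name.
- **Reproducibility**: one master seed; each generator uses an independent
  substream via `SeedSequence(seed, spawn_key=(k,))` with a fixed k per
  generator.

What the generators deliberately do not model: per-gene dispersion trends,
GC and length bias, splice structure, indels, paired-end reads, batch
effects beyond replicate pairing, and correlated expression outside the
explicitly planted modules. Passing recovery tests therefore demonstrates
the statistical machinery is correct under its stated model, not that real
astrocyte data meet that model.

## Xenograft read assignment

The combined reference tags human records `chr|` and mouse records `m.chr|`
and indexes k-mers (default k = 21) per sequence. A read's species score is
the maximum number of its k-mers found in any single sequence of that
species; the larger score wins, equal scores at or above `min_score` are
broken by a seeded uniform random call recorded as a tie (mirroring an
aligner placing a multi-mapping read at one arbitrary top-scored locus; a
`drop_ties` mode discards them instead), and reads below `min_score` on
both sides are unmapped. K-mers containing N never match. Count splitting
is an exact partition: human + mouse + unmapped = total reads.

Exact k-mer scoring stands in for spliced genome alignment; its benchmarks
are therefore property-based — at zero sequence divergence every mapped
read is a tie and the false-assignment rate is ~50 % by construction, and
the rate falls monotonically toward zero as divergence grows past the point
where every read contains species-diagnostic k-mers. Published
false-alignment rates from genome-scale spliced alignment are not
reproducible with this scorer and are not targeted.

## Problem sizes

The validation suite uses 2000 genes with 4–6 samples per group (50 seeds
for null calibration), 600-gene/48-sample block designs for module
recovery, and 1200–4000 reads over 5 transcript pairs per xenosplit
condition — sizes at which every planted effect is comfortably detectable
and the full suite runs in well under a minute of compute per module.

## Known limitations

- The DE test is intentionally minimal: no per-gene dispersion trend
  fitting, no outlier moderation, no independent filtering, unpaired design
  only.
- The adaptive tree cut optimizes a single objective (module count at the
  size floor) and can over- or under-split pathological dendrograms that a
  dynamic cut would handle; the fixed-height mode is available for such
  cases.
- Percentile ranks discard magnitude: a gene can be species-divergent in
  rank while differing modestly in absolute terms, and vice versa.
- The k-mer species scorer ignores base qualities and indels and is not a
  substitute for spliced alignment on real genomes.
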