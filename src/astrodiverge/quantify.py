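"""Normalizations and descriptive comparisons.

RPKM, within-sample percentile ranks, per-gene z-scores, profile
correlations, the Fisher r-to-z two-correlation test, reference-strain ratio
normalization, and single-cell cluster-mean fold-change comparison.

Percentile ranks are the pipeline's cross-species comparison unit: within a
sample, each gene's expression is ranked (average rank for ties) and the rank
``r`` over ``G`` genes is rescaled to ``(r - 1) / (G - 1)`` so the least
expressed gene sits at 0 and the most expressed at 1. Any strictly monotone
transform of a sample's values (library scaling, RPKM length correction with
fixed per-gene lengths does change ranks, pure depth scaling does not) leaves
ranks untouched, which is what makes them comparable across species with
different library compositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionTable, OrthologTable, FormatError

__all__ = [
    "rpkm",
    "percentile_rank",
    "zscore_rows",
    "profile_correlation",
    "compare_correlations",
    "strain_normalize",
    "cluster_mean_foldchange",
    "PercentileMatrix",
]


@dataclass
class PercentileMatrix:
    """Gene x sample matrix of within-sample percentile ranks in [0, 1]."""

    ranks: pd.DataFrame
    source_unit: str = "counts"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.index)


def rpkm(counts: ExpressionTable, lengths: pd.Series) -> ExpressionTable:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM_gs = count_gs / (length_g / 1e3) / (library_s / 1e6)`` where the
    library size is the column sum of the count matrix. Requires a length for
    every gene; errors on a sample with zero total counts.
    """
    if counts.unit != "counts":
        raise ValueError("rpkm expects a raw-count table")
    missing = set(counts.gene_ids) - set(lengths.index)
    if missing:
        raise FormatError(f"genes without length annotation: {sorted(missing)[:5]} ...")
    lib = counts.values.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    kb = lengths.loc[counts.gene_ids].astype(float) / 1e3
    vals = counts.values.div(kb, axis=0).div(lib / 1e6, axis=1)
    return ExpressionTable(vals, counts.meta.copy(), unit="rpkm")


def percentile_rank(expr: ExpressionTable, gene_mask=None) -> PercentileMatrix:
    """Within-sample percentile ranks, average rank on ties, rescaled to [0, 1].

    ``gene_mask`` optionally restricts the ranked universe (e.g. to
    protein-coding genes) before ranking.
    """
    values = expr.values if gene_mask is None else expr.values.loc[list(gene_mask)]
    n_genes = values.shape[0]
    if n_genes < 2:
        raise ValueError("percentile ranks need at least 2 genes")
    r = stats.rankdata(values.to_numpy(), axis=0, method="average")
    ranks = pd.DataFrame((r - 1.0) / (n_genes - 1.0), index=values.index,
                         columns=values.columns)
    return PercentileMatrix(ranks, source_unit=expr.unit)


def zscore_rows(expr: ExpressionTable) -> tuple[pd.DataFrame, pd.Index]:
    """Per-gene z-score across samples: (x - row mean) / row sample sd.

    Rows with zero sample standard deviation are set to 0 and returned in the
    flagged index.
    """
    vals = expr.values
    if vals.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = vals.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z, vals.index[constant]


def profile_correlation(a, b, method: str = "spearman") -> float:
    """Correlation between two expression profiles (Spearman or Pearson)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("profiles must be equal-length 1-d vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided test for a difference between two independent correlations.

    Fisher z-transform each coefficient, z(r) = atanh(r); the statistic
    ``(z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))`` is referred to a standard
    normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n < 4:
            raise ValueError("need n >= 4 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def strain_normalize(expr: ExpressionTable, reference_samples) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene ratio of each non-reference sample to the reference-group mean.

    Used to place samples from different studies on a common scale by
    expressing every gene relative to a shared reference strain (e.g.
    C57BL/6) measured in each study. Genes whose reference mean is zero are
    dropped and reported.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("empty reference sample set")
    ref_mean = expr.values[reference_samples].mean(axis=1)
    dropped = list(expr.values.index[ref_mean == 0])
    keep = ref_mean > 0
    others = [s for s in expr.sample_ids if s not in set(reference_samples)]
    cols = others if others else reference_samples
    ratios = expr.values.loc[keep, cols].div(ref_mean[keep], axis=0)
    return ratios, dropped


def cluster_mean_foldchange(means_a: pd.Series, means_b: pd.Series,
                            orthologs: OrthologTable, eps: float = 0.01) -> pd.DataFrame:
    """Per-ortholog log2 fold change of cluster-mean expression between species.

    ``means_a`` is keyed by human ids, ``means_b`` by mouse ids; both are
    astrocyte-cluster mean expression values. A pseudocount ``eps`` keeps the
    log finite at zero means.
    """
    pairs = orthologs.pairs
    keep = pairs["human"].isin(means_a.index) & pairs["mouse"].isin(means_b.index)
    pairs = pairs.loc[keep]
    if pairs.empty:
        raise ValueError("no overlapping orthologs between the two mean tables")
    a = means_a.loc[pairs["human"]].to_numpy(dtype=float)
    b = means_b.loc[pairs["mouse"]].to_numpy(dtype=float)
    lfc = np.log2(a + eps) - np.log2(b + eps)
    return pd.DataFrame(
        {"human": pairs["human"].to_numpy(), "mouse": pairs["mouse"].to_numpy(),
         "log2fc": lfc}
    ).set_index("human")


def foldchange_correlation(fc_a: pd.Series, fc_b: pd.Series) -> float:
    """Pearson correlation of two per-gene fold-change vectors on shared keys."""
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    return float(stats.pearsonr(fc_a.loc[shared], fc_b.loc[shared]).statistic)
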