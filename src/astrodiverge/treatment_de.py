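"""Treatment-vs-control differential expression and cross-species DEG overlap.

The two-group test is a negative-binomial Wald test on raw counts:

1. size factors by median-of-ratios (geometric-mean reference computed over
   genes with all-positive counts);
2. per-gene NB dispersion (``Var = mu + phi * mu**2``) by method of moments
   on normalized counts, floored at 1e-8 and shrunk 50/50 toward the mean
   dispersion across genes;
3. Wald statistic on the log2 fold change of normalized group means with a
   pseudocount of 0.5, model-based standard error by the delta method;
4. p-values from a t reference with Satterthwaite-style effective degrees of
   freedom for the shrunk dispersion (the 50/50 mix of a ~(n1+n2-2)-df
   genewise estimate with the near-noiseless genewise mean has roughly
   4 * (n1 + n2 - 2) effective df); a plain normal reference is too light in
   the far tail at small n, which matters for FDR control;
5. Benjamini-Hochberg adjustment.

This is a deliberately compact, calibrated two-group test, not a clone of
any particular DE package: the downstream cross-species logic only needs
per-gene fold changes and honest p-values. Genes with all-zero counts in
both groups are untestable and are excluded from the output.

DEG calls use the study's three-way filter: adjusted p < 0.05, linear fold
change > 1.5 in the relevant direction, and average RPKM above 1 in the
control *or* the treated group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionTable, OrthologTable
from .quantify import rpkm

__all__ = [
    "DirectionalGeneSets",
    "nb_two_group_test",
    "deg_filter",
    "cross_species_deg_overlap",
    "effectsize_summary",
]


@dataclass
class DirectionalGeneSets:
    """Up- and downregulated gene-id sets from one comparison."""

    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and downregulated")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    The reference is the per-gene geometric mean over genes with all-positive
    counts; each sample's factor is the median ratio to that reference.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts; cannot normalize")
    ref = np.exp(np.log(counts.loc[positive]).mean(axis=1))
    sf = counts.loc[positive].div(ref, axis=0).median(axis=0)
    return sf


def nb_two_group_test(counts: ExpressionTable, control_samples, treated_samples,
                      lengths: pd.Series | None = None) -> pd.DataFrame:
    """NB Wald test of treated vs control; returns a per-gene DEG table.

    Columns: ``log2fc`` (treated over control), ``p``, ``fdr``,
    ``mean_norm_control``, ``mean_norm_treated`` and, when gene ``lengths``
    are supplied, ``mean_rpkm_control`` / ``mean_rpkm_treated`` (otherwise
    those columns carry the normalized-count means as an expression-level
    proxy).
    """
    control_samples, treated_samples = list(control_samples), list(treated_samples)
    if len(control_samples) < 2 or len(treated_samples) < 2:
        raise ValueError("need >= 2 samples per group")
    if counts.unit != "counts":
        raise ValueError("nb_two_group_test expects raw counts")
    sub = counts.values[control_samples + treated_samples]
    for name, cols in (("control", control_samples), ("treated", treated_samples)):
        if sub[cols].to_numpy().sum() == 0:
            raise ValueError(f"{name} group has zero total counts")

    testable = sub.sum(axis=1) > 0
    sub = sub.loc[testable]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    c = norm[control_samples].to_numpy()
    t = norm[treated_samples].to_numpy()
    n_c, n_t = c.shape[1], t.shape[1]

    m_c, m_t = c.mean(axis=1), t.mean(axis=1)
    v_c, v_t = c.var(axis=1, ddof=1), t.var(axis=1, ddof=1)
    # pooled within-group moment estimate of phi in Var = mu + phi mu^2
    grand = (m_c * n_c + m_t * n_t) / (n_c + n_t)
    pooled_var = (v_c * (n_c - 1) + v_t * (n_t - 1)) / (n_c + n_t - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (pooled_var - grand) / grand**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    phi = np.maximum(phi, 1e-8)
    phi = 0.5 * phi + 0.5 * phi.mean()

    pc = 0.5
    lfc = np.log2(m_t + pc) - np.log2(m_c + pc)
    var_mean_c = (m_c + phi * m_c**2) / n_c
    var_mean_t = (m_t + phi * m_t**2) / n_t
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_mean_c / ((m_c + pc) ** 2 * ln2sq)
                 + var_mean_t / ((m_t + pc) ** 2 * ln2sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    df_eff = 4 * (n_c + n_t - 2)
    p = 2.0 * stats.t.sf(np.abs(z), df_eff)
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {"log2fc": lfc, "p": p, "fdr": fdr,
         "mean_norm_control": m_c, "mean_norm_treated": m_t},
        index=sub.index,
    )
    if lengths is not None:
        rk = rpkm(counts.subset_samples(control_samples + treated_samples), lengths)
        out["mean_rpkm_control"] = rk.values.loc[sub.index, control_samples].mean(axis=1)
        out["mean_rpkm_treated"] = rk.values.loc[sub.index, treated_samples].mean(axis=1)
    else:
        out["mean_rpkm_control"] = m_c
        out["mean_rpkm_treated"] = m_t
    return out


def deg_filter(table: pd.DataFrame, fdr_cut: float = 0.05, fc_cut: float = 1.5,
               rpkm_cut: float = 1.0) -> DirectionalGeneSets:
    """Directional DEG sets at FDR, fold-change and expression-level cuts.

    ``up``: fdr < fdr_cut, linear fold change 2**log2fc > fc_cut, and mean
    RPKM of the control or treated group > rpkm_cut; ``down`` symmetric with
    2**(-log2fc) > fc_cut.
    """
    expressed = (table["mean_rpkm_control"] > rpkm_cut) | (table["mean_rpkm_treated"] > rpkm_cut)
    sig = (table["fdr"] < fdr_cut) & expressed
    up = set(table.index[sig & (2.0 ** table["log2fc"] > fc_cut)])
    down = set(table.index[sig & (2.0 ** (-table["log2fc"]) > fc_cut)])
    return DirectionalGeneSets(up=up, down=down)


def cross_species_deg_overlap(human: DirectionalGeneSets, mouse: DirectionalGeneSets,
                              orthologs: OrthologTable) -> pd.DataFrame:
    """Per-direction overlap between human and mouse DEG sets.

    Mouse ids are mapped to human ids through the ortholog table before
    intersecting. The percentage is 100 * |overlap| / |human set|, i.e. the
    share of the human response conserved in mouse. Returns one row per
    direction with columns ``n_human``, ``n_mouse``, ``n_overlap``,
    ``pct_of_human``, plus Venn counts ``human_only`` / ``mouse_only``.
    """
    m2h = orthologs.mouse_to_human()
    rows = {}
    for direction, hset, mset in (("up", human.up, mouse.up), ("down", human.down, mouse.down)):
        mapped = {m2h[g] for g in mset if g in m2h}
        k = len(hset & mapped)
        if len(hset) == 0:
            raise ValueError(f"empty human {direction} set: percentage undefined")
        rows[direction] = {
            "n_human": len(hset),
            "n_mouse": len(mset),
            "n_overlap": k,
            "pct_of_human": 100.0 * k / len(hset),
            "human_only": len(hset) - k,
            "mouse_only": len(mapped) - k,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def estimate_conserved_fraction(overlap: pd.DataFrame) -> float:
    """Estimate the conserved fraction of the treatment response from overlap counts.

    Pooled over directions: conserved ~= |A and B| / |A or B|, i.e. genes
    called in both species over genes called in either (after ortholog
    mapping). Imperfect per-species recall deflates the numerator once and
    the denominator partially, so the estimate is mildly conservative.
    """
    k = overlap["n_overlap"].sum()
    union = (overlap["n_human"] + overlap["n_mouse"] - overlap["n_overlap"]).sum()
    if union == 0:
        raise ValueError("no DEG called in either species")
    return float(k / union)


def effectsize_summary(table_h: pd.DataFrame, table_m: pd.DataFrame,
                       orthologs: OrthologTable) -> tuple[float, float, int]:
    """Pearson correlation of per-ortholog log2 fold changes between species.

    Returns (r, two-sided p, number of shared tested orthologs).
    """
    pairs = orthologs.pairs
    keep = pairs["human"].isin(table_h.index) & pairs["mouse"].isin(table_m.index)
    pairs = pairs.loc[keep]
    if len(pairs) < 3:
        raise ValueError("need >= 3 shared tested orthologs")
    a = table_h.loc[pairs["human"], "log2fc"].to_numpy()
    b = table_m.loc[pairs["mouse"], "log2fc"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant fold-change vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), len(pairs)
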