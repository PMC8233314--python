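"""Cross-species divergence testing on percentile ranks.

For each one-to-one ortholog pair the human and mouse per-sample percentile
ranks are compared with Welch's unequal-variance t-test, followed by
Benjamini-Hochberg FDR (or Bonferroni) adjustment over the post-filter
ortholog set. Genes whose maximal percentile rank across all samples of both
species falls below 1/3 are excluded first, removing genes not expressed (or
expressed at very low levels) in either species. A gene is called divergent
when its adjusted p falls below the FDR cut *and* its mean-rank difference
exceeds the rank-difference cut (default 0.4), both strict inequalities.

``rank_diff`` (human mean rank minus mouse mean rank, the "hmDiff" axis) is
also the quantity correlated across datasets, e.g. acutely purified vs
xenografted astrocytes, to ask whether species differences persist across
conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OrthologTable
from .quantify import PercentileMatrix

__all__ = [
    "filter_expressed",
    "species_diff_test",
    "classify_divergent",
    "hmdiff_correlate",
]


def filter_expressed(perc_h: PercentileMatrix, perc_m: PercentileMatrix,
                     orthologs: OrthologTable, threshold: float = 1.0 / 3.0) -> OrthologTable:
    """Retain ortholog pairs whose max percentile over all samples >= threshold.

    The default threshold of 1/3 keeps genes ranked in the top two-thirds of
    at least one sample of either species.
    """
    pairs = orthologs.pairs
    keep_idx = pairs["human"].isin(perc_h.ranks.index) & pairs["mouse"].isin(perc_m.ranks.index)
    pairs = pairs.loc[keep_idx]
    max_h = perc_h.ranks.loc[pairs["human"]].max(axis=1).to_numpy()
    max_m = perc_m.ranks.loc[pairs["mouse"]].max(axis=1).to_numpy()
    retained = np.maximum(max_h, max_m) >= threshold
    out = OrthologTable(pairs.loc[retained].reset_index(drop=True))
    if len(out) == 0:
        raise ValueError("no ortholog pair passes the expression filter")
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t over rows; handles zero-variance rows explicitly.

    Returns (t, p, degenerate_flag). Rows where both groups have zero
    variance get p=1 at equal means, p=0 (flagged) at unequal means.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    equal = degenerate & (m1 == m2)
    unequal = degenerate & (m1 != m2)
    t[equal], p[equal] = 0.0, 1.0
    t[unequal] = np.sign(m1 - m2)[unequal] * np.inf
    p[unequal] = 0.0
    return t, p, degenerate & unequal


def species_diff_test(perc_h: PercentileMatrix, perc_m: PercentileMatrix,
                      orthologs: OrthologTable, adjust: str = "bh") -> pd.DataFrame:
    """Per-ortholog Welch t-test of percentile ranks between species.

    Returns a table indexed by human gene id with columns ``mouse``,
    ``mean_rank_human``, ``mean_rank_mouse``, ``rank_diff`` (human minus
    mouse), ``welch_t``, ``p``, ``p_adj``, ``max_rank_overall`` and
    ``degenerate`` (zero variance with unequal means). ``adjust`` selects
    Benjamini-Hochberg (``"bh"``) or Bonferroni (``"bonferroni"``).
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    pairs = orthologs.pairs
    h = perc_h.ranks.loc[pairs["human"]].to_numpy()
    m = perc_m.ranks.loc[pairs["mouse"]].to_numpy()
    if h.shape[1] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 samples per species")
    t, p, flagged = _welch(h, m)
    p_adj = multipletests(p, method="fdr_bh" if adjust == "bh" else "bonferroni")[1]
    return pd.DataFrame(
        {
            "mouse": pairs["mouse"].to_numpy(),
            "mean_rank_human": h.mean(axis=1),
            "mean_rank_mouse": m.mean(axis=1),
            "rank_diff": h.mean(axis=1) - m.mean(axis=1),
            "welch_t": t,
            "p": p,
            "p_adj": p_adj,
            "max_rank_overall": np.maximum(h.max(axis=1), m.max(axis=1)),
            "degenerate": flagged,
        },
        index=pd.Index(pairs["human"].to_numpy(), name="human"),
    )


def classify_divergent(table: pd.DataFrame, fdr_cut: float = 0.05,
                       diff_cut: float = 0.4) -> tuple[set[str], set[str], set[str]]:
    """Split orthologs into (human_higher, mouse_higher, similar) sets.

    Divergence requires adjusted p strictly below ``fdr_cut`` and a rank
    difference strictly above ``diff_cut`` in the corresponding direction.
    """
    sig = table["p_adj"] < fdr_cut
    human_higher = set(table.index[sig & (table["rank_diff"] > diff_cut)])
    mouse_higher = set(table.index[sig & (table["rank_diff"] < -diff_cut)])
    similar = set(table.index) - human_higher - mouse_higher
    return human_higher, mouse_higher, similar


def hmdiff_correlate(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     gene_subset=None) -> float:
    """Pearson correlation of rank_diff between two divergence tables.

    Measures whether species differences found in one dataset (e.g. acutely
    purified astrocytes) persist in another (e.g. xenografted astrocytes).
    """
    shared = table_a.index.intersection(table_b.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(list(gene_subset)))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared orthologs")
    a = table_a.loc[shared, "rank_diff"].to_numpy()
    b = table_b.loc[shared, "rank_diff"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank_diff vector is constant")
    return float(stats.pearsonr(a, b).statistic)
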