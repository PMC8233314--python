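"""Gene-set overlap enrichment, directional concordance, core signatures.

``overlap_enrichment`` asks whether two gene sets drawn from a common
background of N genes share more members than chance predicts: the expected
overlap of random same-size sets is ``n1 * n2 / N``, the fold (representation
factor) is observed over expected, and the p-value is the exact
hypergeometric upper tail P(X >= k).

``direction_concordance`` crosses two up/down DEG list pairs into a 2x2
table (up/up, up/down, down/up, down/down over genes differential in both
comparisons) and tests association with a two-sided Fisher exact test, or a
chi-square test (no continuity correction) when the table total is >= 1000;
if any expected cell is below 5 the chi-square falls back to Fisher and the
fallback is recorded. Bonferroni correction over the comparison family is
applied on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .treatment_de import DirectionalGeneSets

__all__ = [
    "OverlapResult",
    "ConcordanceResult",
    "overlap_enrichment",
    "direction_concordance",
    "core_signature",
]

CHI2_MIN_TOTAL = 1000  # table total at/above which chi-square replaces Fisher


@dataclass
class OverlapResult:
    N: int
    n1: int
    n2: int
    k: int
    expected: float
    fold: float
    p: float


@dataclass
class ConcordanceResult:
    table: tuple[int, int, int, int]  # (upA&upB, upA&downB, downA&upB, downA&downB)
    test_used: str  # "fisher" or "chi2"
    fallback: bool  # chi2 requested by size rule but expected cell < 5
    odds_ratio: float
    p: float
    p_adjusted: float
    direction: str  # "concordant", "anticorrelated", "none"


def overlap_enrichment(N: int, set_a, set_b, background=None) -> OverlapResult:
    """Hypergeometric overlap enrichment of two sets on a background of size N.

    ``background`` (optional) enables membership validation; N must always be
    supplied explicitly by the caller — a silently defaulted background makes
    enrichment p-values irreproducible.
    """
    set_a, set_b = set(set_a), set(set_b)
    if background is not None:
        background = set(background)
        if len(background) != N:
            raise ValueError("N does not match the supplied background")
        stray = (set_a | set_b) - background
        if stray:
            raise ValueError(f"elements outside background: {sorted(stray)[:5]}")
    if N < max(len(set_a), len(set_b)):
        raise ValueError("N smaller than a set size")
    n1, n2 = len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n1 * n2 / N
    fold = k / expected if expected > 0 else 0.0
    # P(X >= k) with X ~ Hypergeom(N, n1, n2)
    p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    return OverlapResult(N=N, n1=n1, n2=n2, k=k, expected=expected, fold=fold,
                         p=min(p, 1.0))


def concordance_table(a: DirectionalGeneSets, b: DirectionalGeneSets) -> tuple[int, int, int, int]:
    """Counts of (upA&upB, upA&downB, downA&upB, downA&downB)."""
    return (
        len(a.up & b.up),
        len(a.up & b.down),
        len(a.down & b.up),
        len(a.down & b.down),
    )


def direction_concordance(a: DirectionalGeneSets, b: DirectionalGeneSets,
                          family_size: int = 1,
                          alpha: float = 0.05) -> ConcordanceResult:
    """Test directional agreement of two DEG list pairs on shared ids."""
    aa, bb, cc, dd = concordance_table(a, b)
    total = aa + bb + cc + dd
    if total == 0:
        raise ValueError("no gene is differential in both comparisons")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    table = np.array([[aa, bb], [cc, dd]])
    use_chi2 = total >= CHI2_MIN_TOTAL
    fallback = False
    if use_chi2:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        if (expected < 5).any():
            use_chi2, fallback = False, True
    if use_chi2:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)[:4]
        test_used = "chi2"
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        test_used = "fisher"
    odds = (aa * dd) / (bb * cc) if bb * cc > 0 else np.inf if aa * dd > 0 else np.nan
    p_adj = min(1.0, float(p) * family_size)
    if p_adj < alpha and aa * dd > bb * cc:
        direction = "concordant"
    elif p_adj < alpha and aa * dd < bb * cc:
        direction = "anticorrelated"
    else:
        direction = "none"
    return ConcordanceResult(table=(aa, bb, cc, dd), test_used=test_used,
                             fallback=fallback, odds_ratio=float(odds), p=float(p),
                             p_adjusted=p_adj, direction=direction)


def core_signature(set_pairs: list[DirectionalGeneSets]) -> tuple[set[str], set[str]]:
    """Genes consistently up (resp. down) across every comparison.

    The core up set is the intersection of all ``up`` sets and likewise for
    ``down``; a gene discordant in any comparison drops out by construction.
    """
    if len(set_pairs) < 2:
        raise ValueError("need at least two comparisons")
    core_up = set.intersection(*(sp.up for sp in set_pairs))
    core_down = set.intersection(*(sp.down for sp in set_pairs))
    return core_up, core_down
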