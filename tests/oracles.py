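"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain loops
and literal arithmetic, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math


def brute_gene_log2fc(
    counts: dict[str, dict[str, int]],
    conditions: dict[str, str],
    gene_guides: list[str],
    nt_guides: list[str],
    pseudocount: float,
) -> float:
    """L_g by explicit summation; counts[sample][guide]."""

    def pooled(guides, cond):
        total = 0
        for s, c in conditions.items():
            if c != cond:
                continue
            for g in guides:
                total += counts[s][g]
        return total

    g_h = pooled(gene_guides, "hPi")
    g_c = pooled(gene_guides, "control")
    n_h = pooled(nt_guides, "hPi")
    n_c = pooled(nt_guides, "control")
    pc = pseudocount
    return math.log2((g_h + pc) / (n_h + pc)) - math.log2((g_c + pc) / (n_c + pc))


def brute_empirical_p(stat: float, null_stats: list[float]) -> float:
    """Two-sided add-one empirical p around the null median."""
    ordered = sorted(null_stats)
    n = len(ordered)
    if n % 2:
        m = ordered[n // 2]
    else:
        m = (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    hits = sum(1 for x in null_stats if abs(x - m) >= abs(stat - m))
    return (hits + 1) / (n + 1)


def brute_bh(pvalues: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = pvalues[i] * m / rank_from_top
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


def brute_venn(named_sets: dict[str, set[str]]) -> dict[tuple[bool, ...], set[str]]:
    """Membership regions by scanning every gene of the union."""
    names = list(named_sets)
    union = set().union(*named_sets.values())
    regions: dict[tuple[bool, ...], set[str]] = {}
    for gene in union:
        pattern = tuple(gene in named_sets[n] for n in names)
        regions.setdefault(pattern, set()).add(gene)
    return regions


def brute_auroc(pos_scores: list[float], neg_scores: list[float]) -> float:
    """AUROC by pairwise comparison (ties count half)."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
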