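"""Independent reference computations used as oracles in tests.

These deliberately take the slow, obviously-correct route (per-bp
counting, double loops, exact rational hypergeometric sums) and never
share code with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def naive_coverage(segments_by_sample, chrom, chrom_len):
    """Per-bp sample coverage by counting, one base at a time."""
    cov = np.zeros(chrom_len, dtype=int)
    for segs in segments_by_sample.values():
        for iv in segs:
            if iv.chrom == chrom:
                cov[iv.start : iv.end] += 1
    return cov


def naive_gene_score(gene, collective_segments):
    """Double-loop gene score: every segment, explicit overlap test."""
    total = 0.0
    n = 0
    for seg in collective_segments:
        if seg.chrom != gene.chrom:
            continue
        overlap = min(seg.end, gene.interval.end) - max(seg.start, gene.interval.start)
        if overlap >= 1:
            total += seg.sample_count / (seg.length + gene.length)
            n += 1
    return total, n


def hypergeom_tail_greater(table) -> float:
    """Exact one-sided (greater) Fisher p by rational tail summation.

    For table [[a, b], [c, d]]: P(X >= a) where X is hypergeometric with
    population N = a+b+c+d, K = a+b successes, draws n = a+c.
    """
    (a, b), (c, d) = table
    N = a + b + c + d
    K = a + b
    n = a + c
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
    return float(total)


def reference_by_adjust(pvals):
    """Benjamini-Yekutieli step-up via the statsmodels implementation."""
    from statsmodels.stats.multitest import multipletests

    _rej, padj, _a, _b = multipletests(pvals, method="fdr_by")
    return padj


def rank_based_spearman(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks."""
    import pandas as pd

    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    return float(np.corrcoef(rx, ry)[0, 1])
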