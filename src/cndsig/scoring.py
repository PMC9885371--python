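"""Gene score against a collective deletion track.

For gene *g* with length ``L_g`` the score sums, over the ``N`` collective
segments *i* that intersect the gene by at least 1 bp,

    Score_g = sum_i  S_i / (L_i + L_g)

where ``S_i`` is the segment's sample count and ``L_i`` its length (bp).
The score rewards recurrence across samples and penalizes long segments
and long genes; its unit is 1/bp and it is only compared within one
analysis, where units cancel in the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GeneRecord, InputError
from .track import CollectiveTrack


@dataclass(frozen=True)
class GeneScore:
    symbol: str
    score: float
    n_overlapping: int


def gene_score(gene: GeneRecord, track: CollectiveTrack) -> GeneScore:
    """Score one gene; segments on other chromosomes contribute nothing."""
    starts, ends, counts = track.arrays(gene.chrom)
    if starts.size == 0:
        return GeneScore(gene.symbol, 0.0, 0)
    # Collective segments are sorted and disjoint within a chromosome, so
    # the overlapping ones form the contiguous slice [lo, hi).
    lo = int(np.searchsorted(ends, gene.interval.start, side="right"))
    hi = int(np.searchsorted(starts, gene.interval.end, side="left"))
    if hi <= lo:
        return GeneScore(gene.symbol, 0.0, 0)
    lengths = ends[lo:hi] - starts[lo:hi]
    score = float(np.sum(counts[lo:hi] / (lengths + gene.length)))
    return GeneScore(gene.symbol, score, hi - lo)


def score_all_genes(
    annotation: list[GeneRecord], track: CollectiveTrack
) -> dict[str, GeneScore]:
    """Score every gene; equivalent to independent :func:`gene_score` calls."""
    if not annotation:
        raise InputError("empty gene annotation")
    return {gene.symbol: gene_score(gene, track) for gene in annotation}
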