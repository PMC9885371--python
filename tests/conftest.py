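from __future__ import annotations

import numpy as np
import pytest

from cndsig.core import (
    ChromosomeSizes,
    GeneRecord,
    GenomicInterval,
    SampleSegmentSet,
)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def gene(symbol, chrom, start, end):
    return GeneRecord(symbol, GenomicInterval(chrom, start, end))


def random_cohort(rng, n_samples=5, chrom_len=10_000, max_segs=4, chrom="chr1"):
    """Small random cohort for oracle comparisons."""
    samples = {}
    for s in range(n_samples):
        segs = []
        for _ in range(rng.integers(0, max_segs + 1)):
            start = int(rng.integers(0, chrom_len - 1))
            end = int(rng.integers(start + 1, chrom_len + 1))
            segs.append(GenomicInterval(chrom, start, end))
        samples[f"S{s}"] = segs
    return SampleSegmentSet(samples)


@pytest.fixture
def sizes_10kb():
    return ChromosomeSizes({"chr1": 10_000, "chr2": 10_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
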