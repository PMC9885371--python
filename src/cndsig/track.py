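"""Collapse a cohort's deletion segments into the collective track.

The collective track partitions each chromosome at every distinct sample
segment boundary. Each maximal run between consecutive breakpoints with
per-bp coverage >= 1 becomes one :class:`~cndsig.core.CollectiveSegment`
carrying its length and the number of covering samples. Atoms are never
merged across breakpoints, even when adjacent atoms happen to share the
same sample count: the partition is defined purely by distinct breakpoints
because each atom is a separate term of the gene score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CollectiveSegment,
    GenomicInterval,
    InputError,
    SampleSegmentSet,
)


@dataclass
class CollectiveTrack:
    """Per-chromosome ordered collective segments plus provenance."""

    segments: dict[str, list[CollectiveSegment]]
    n_samples: int
    n_input_segments: int
    _arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def chroms(self) -> list[str]:
        return sorted(self.segments)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, sample_counts) as int64 arrays, cached per chrom."""
        if chrom not in self._arrays:
            segs = self.segments.get(chrom, [])
            self._arrays[chrom] = (
                np.array([s.start for s in segs], dtype=np.int64),
                np.array([s.end for s in segs], dtype=np.int64),
                np.array([s.sample_count for s in segs], dtype=np.int64),
            )
        return self._arrays[chrom]

    def all_segments(self) -> list[CollectiveSegment]:
        return [s for chrom in self.chroms() for s in self.segments[chrom]]

    @property
    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())

    @property
    def weighted_bp(self) -> int:
        """Sum of sample_count * length over all collective segments.

        Equals the cohort's total deleted bp (conservation invariant).
        """
        return sum(s.sample_count * s.length for s in self.all_segments())

    def to_bed(self, path: str | Path) -> None:
        """Export as BED4 with the sample count in the name column."""
        with open(path, "w") as fh:
            for seg in self.all_segments():
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.sample_count}\n")


def build_collective_track(cohort: SampleSegmentSet) -> CollectiveTrack:
    """Partition the cohort's deletions at every distinct segment boundary.

    Each atom with coverage >= 1 becomes a collective segment whose
    ``sample_count`` is the number of samples deleted there; zero-coverage
    gaps are excluded. Because per-sample segments are normalized, coverage
    equals the number of covering samples.
    """
    if cohort.n_samples == 0:
        raise InputError("cannot build a collective track from an empty cohort")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_input = 0
    for _sample, segs in cohort.items():
        for iv in segs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            n_input += 1
    out: dict[str, list[CollectiveSegment]] = {}
    for chrom in sorted(by_chrom):
        pairs = np.array(by_chrom[chrom], dtype=np.int64)
        starts, ends = pairs[:, 0], pairs[:, 1]
        bounds = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(bounds.size, dtype=np.int64)
        np.add.at(delta, np.searchsorted(bounds, starts), 1)
        np.add.at(delta, np.searchsorted(bounds, ends), -1)
        coverage = np.cumsum(delta)[:-1]  # constant on [bounds[i], bounds[i+1])
        keep = coverage > 0
        out[chrom] = [
            CollectiveSegment(GenomicInterval(chrom, int(b0), int(b1)), int(c))
            for b0, b1, c in zip(bounds[:-1][keep], bounds[1:][keep], coverage[keep])
        ]
    return CollectiveTrack(
        segments=out, n_samples=cohort.n_samples, n_input_segments=n_input
    )


def breakpoints(cohort: SampleSegmentSet) -> dict[str, list[int]]:
    """Multiset of segment endpoints per chromosome, sorted.

    Each sample segment contributes its start and its end; multiplicity
    across samples is preserved (two samples sharing a boundary yield two
    breakpoints at that position).
    """
    out: dict[str, list[int]] = {}
    for _sample, segs in cohort.items():
        for iv in segs:
            lst = out.setdefault(iv.chrom, [])
            lst.append(iv.start)
            lst.append(iv.end)
    return {chrom: sorted(positions) for chrom, positions in sorted(out.items())}
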