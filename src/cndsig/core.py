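"""Genomic coordinate primitives shared across the package.

Conventions
-----------
All coordinates are 0-based, half-open ``[start, end)``, matching BED:
interval length is ``end - start`` and book-ended intervals share no base.
Readers for 1-based formats convert on ingest. Chromosome names are taken
verbatim from input; no ``chr``-prefix rewriting is performed.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path


class CndSigError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CndSigError):
    """Malformed or inconsistent input data."""


class ConfigError(CndSigError):
    """Invalid configuration value."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise InputError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 if disjoint).

    Intervals on different chromosomes never overlap; half-open adjacency
    (``a.end == b.start``) counts as zero overlap.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class ChromosomeSizes(Mapping[str, int]):
    """Mapping of chromosome name to length in bp.

    Defines the genome build for an analysis: shuffling bounds, breakpoint
    enrichment footprints and strict input validation all consult it.
    """

    def __init__(self, sizes: Mapping[str, int]):
        if not sizes:
            raise InputError("chromosome sizes table is empty")
        clean: dict[str, int] = {}
        for name, length in sizes.items():
            name = str(name)
            length = int(length)
            if length <= 0:
                raise InputError(f"non-positive length for chromosome {name!r}")
            if name in clean:
                raise InputError(f"duplicate chromosome name {name!r}")
            clean[name] = length
        self._sizes = clean

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def validate_interval(self, interval: GenomicInterval) -> None:
        """Raise :class:`InputError` unless the interval fits this genome."""
        if interval.chrom not in self._sizes:
            raise InputError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise InputError(
                f"interval {interval} exceeds chromosome length "
                f"{self._sizes[interval.chrom]}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromosomeSizes":
        """Read a two-column (name, length) tab-delimited table."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InputError(f"{path}:{lineno}: expected two columns")
                try:
                    length = int(fields[1])
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: non-numeric length") from exc
                if fields[0] in sizes:
                    raise InputError(f"{path}:{lineno}: duplicate chromosome")
                sizes[fields[0]] = length
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GeneRecord:
    """A gene symbol with its genomic interval; supplies the gene length
    term of the gene score."""

    symbol: str
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class CollectiveSegment:
    """One breakpoint-bounded atom of the cohort-wide deletion track.

    ``sample_count`` is the number of cohort samples whose deletion covers
    every base of the atom (coverage is constant within an atom by
    construction).
    """

    interval: GenomicInterval
    sample_count: int

    def __post_init__(self) -> None:
        if self.sample_count < 1:
            raise InputError("collective segment must be covered by >= 1 sample")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def normalize_sample(segments: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort per chromosome and merge overlapping or book-ended intervals.

    A deletion split by the caller at an internal point is one event for
    sample-counting purposes, so book-ended (``end == next start``)
    intervals merge. Idempotent; preserves total covered bp.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in segments:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


class SampleSegmentSet:
    """Per-sample deletion intervals for a cohort.

    Segments are normalized on construction, so within one sample and
    chromosome the stored intervals are pairwise non-overlapping, non
    book-ended and sorted. Samples with no deletions are permitted (and
    retained: they are still cohort members).
    """

    def __init__(
        self,
        segments: Mapping[str, Iterable[GenomicInterval]],
        sizes: ChromosomeSizes | None = None,
    ):
        data: dict[str, list[GenomicInterval]] = {}
        for sample in sorted(segments):
            segs = list(segments[sample])
            data[str(sample)] = normalize_sample(segs) if segs else []
        if sizes is not None:
            for segs in data.values():
                for iv in segs:
                    sizes.validate_interval(iv)
        self._data = data

    @property
    def samples(self) -> list[str]:
        return list(self._data)

    @property
    def n_samples(self) -> int:
        return len(self._data)

    def __getitem__(self, sample: str) -> list[GenomicInterval]:
        return self._data[sample]

    def items(self) -> Iterable[tuple[str, list[GenomicInterval]]]:
        return self._data.items()

    @property
    def total_segments(self) -> int:
        return sum(len(v) for v in self._data.values())

    @property
    def total_deleted_bp(self) -> int:
        """Sum over samples of union-deleted bp (post-normalization)."""
        return sum(iv.length for segs in self._data.values() for iv in segs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSegmentSet):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleSegmentSet(n_samples={self.n_samples}, "
            f"total_segments={self.total_segments})"
        )
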