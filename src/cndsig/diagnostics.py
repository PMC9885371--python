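"""Model-motivating diagnostics: gene-hit-frequency decay and breakpoint
enrichment in driver genes.

Gene hit frequency (GHF) of a collective segment is the number of genes it
intersects per 100 kb of segment length. Each of the segment's covering
samples contributes one logical record ("one gene deletion event"), so
records are weighted by the sample count rather than multiplying the GHF
value itself. The decay of GHF with segment size motivates the length
penalty in the gene score.

Breakpoint enrichment asks whether segment endpoints fall inside a curated
driver-gene footprint more often than the footprint's share of the genome
would predict. The 2x2 construction used here is an explicit, documented
convention (the contrast cell counts footprint bp without a breakpoint);
the length-corrected mode dichotomizes per-gene breakpoint *rates*
(count / gene length) at the genome-wide median instead, removing the
advantage long genes have at catching breakpoints.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneRecord, InputError, SampleSegmentSet, normalize_sample
from .core import ChromosomeSizes
from .track import CollectiveTrack, breakpoints

GHF_BIN_BP = 100_000


def ghf_records(track: CollectiveTrack, annotation: list[GeneRecord]) -> pd.DataFrame:
    """One row per collective segment with its gene-hit frequency.

    Columns: chrom, start, end, length, sample_count (the record weight),
    n_genes_hit (>= 1 bp overlap), ghf (genes per 100 kb) and bin_index
    (floor(length / 100 kb)). Zero-hit segments are retained with ghf 0.
    """
    gene_starts: dict[str, list[int]] = {}
    gene_ends: dict[str, list[int]] = {}
    for g in annotation:
        gene_starts.setdefault(g.chrom, []).append(g.interval.start)
        gene_ends.setdefault(g.chrom, []).append(g.interval.end)
    for chrom in gene_starts:
        gene_starts[chrom].sort()
        gene_ends[chrom].sort()

    rows = []
    for seg in track.all_segments():
        starts = gene_starts.get(seg.chrom, [])
        ends = gene_ends.get(seg.chrom, [])
        # genes not overlapping are entirely left (end <= seg.start) or
        # entirely right (start >= seg.end); valid even for overlapping genes
        n_hit = bisect_left(starts, seg.end) - bisect_right(ends, seg.start)
        rows.append(
            {
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "length": seg.length,
                "sample_count": seg.sample_count,
                "n_genes_hit": n_hit,
                "ghf": n_hit / (seg.length / GHF_BIN_BP),
                "bin_index": seg.length // GHF_BIN_BP,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "sample_count",
            "n_genes_hit", "ghf", "bin_index",
        ],
    )


def ghf_summary(
    records: pd.DataFrame,
    bin_width: int = GHF_BIN_BP,
    max_size: int = 5_000_000,
) -> tuple[pd.DataFrame, float, float]:
    """Per-size-bin GHF quartiles plus the weighted Spearman correlation.

    Records are expanded by their sample-count weight (each covering sample
    is one event), then binned by segment length into ``[k*bin_width,
    (k+1)*bin_width)`` up to ``max_size``. Returns ``(bin_table, rho, pval)``
    where rho is the Spearman correlation of (length, ghf) on the expanded
    set. Raises on degenerate input (fewer than two distinct lengths).
    """
    if len(records) == 0:
        raise InputError("no GHF records")
    idx = np.repeat(np.arange(len(records)), records["sample_count"].to_numpy())
    lengths = records["length"].to_numpy()[idx]
    ghf = records["ghf"].to_numpy()[idx]
    if np.unique(lengths).size < 2:
        raise InputError("GHF correlation undefined: all segment lengths equal")
    if np.all(ghf == ghf[0]):
        rho, pval = 0.0, 1.0  # rank correlation of a constant: no trend
    else:
        res = stats.spearmanr(lengths, ghf)
        rho, pval = float(res.statistic), float(res.pvalue)

    in_range = lengths < max_size
    bins = lengths[in_range] // bin_width
    frame = pd.DataFrame({"bin_index": bins, "ghf": ghf[in_range]})
    grouped = frame.groupby("bin_index")["ghf"]
    table = grouped.agg(
        n_events="size",
        q25=lambda x: float(np.percentile(x, 25)),
        median="median",
        q75=lambda x: float(np.percentile(x, 75)),
    ).reset_index()
    table["bin_start"] = table["bin_index"] * bin_width
    table["bin_end"] = (table["bin_index"] + 1) * bin_width
    return table, rho, pval


@dataclass(frozen=True)
class BreakpointEnrichmentResult:
    """2x2 contingency table with its one-sided Fisher test."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float
    mode: str  # "gene-level" | "length-corrected"

    def to_metadata(self) -> dict:
        return {
            "mode": self.mode,
            "table": [list(self.table[0]), list(self.table[1])],
            "odds_ratio": self.odds_ratio,
            "pvalue": self.pvalue,
        }


def _fisher_greater(table) -> tuple[float, float]:
    res = stats.fisher_exact(np.asarray(table), alternative="greater")
    return float(res.statistic), float(res.pvalue)


def _merged_footprint(
    genes: list[GeneRecord],
) -> tuple[dict[str, tuple[list[int], list[int]]], int]:
    """Union of gene intervals per chromosome: (starts, ends) sorted, + bp."""
    merged = normalize_sample([g.interval for g in genes])
    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    total = 0
    for iv in merged:
        starts, ends = per_chrom.setdefault(iv.chrom, ([], []))
        starts.append(iv.start)
        ends.append(iv.end)
        total += iv.length
    return per_chrom, total


def _in_footprint(
    footprint: dict[str, tuple[list[int], list[int]]], chrom: str, pos: int
) -> bool:
    """Half-open containment: pos is inside iff start <= pos < end."""
    if chrom not in footprint:
        return False
    starts, ends = footprint[chrom]
    i = bisect_right(starts, pos) - 1
    return i >= 0 and pos < ends[i]


def breakpoint_gene_enrichment(
    cohort: SampleSegmentSet,
    annotation: list[GeneRecord],
    driver_set: set[str],
    sizes: ChromosomeSizes,
) -> BreakpointEnrichmentResult:
    """Are breakpoints over-represented inside the driver-gene footprint?

    Rows: breakpoint position inside the (merged) driver footprint vs
    outside. Columns: observed breakpoints (with multiplicity) vs remaining
    bp of the corresponding footprint without a breakpoint (distinct
    positions subtracted, so cells stay non-negative). One-sided Fisher
    (greater) tests over-representation.
    """
    drivers = [g for g in annotation if g.symbol in driver_set]
    if not drivers:
        raise InputError("driver set does not intersect the annotation")
    bps = breakpoints(cohort)
    n_bp = sum(len(v) for v in bps.values())
    if n_bp == 0:
        raise InputError("empty breakpoint multiset")
    footprint, driver_bp = _merged_footprint(drivers)

    in_driver = 0
    distinct_in: set[tuple[str, int]] = set()
    distinct_out: set[tuple[str, int]] = set()
    for chrom, positions in bps.items():
        for pos in positions:
            if _in_footprint(footprint, chrom, pos):
                in_driver += 1
                distinct_in.add((chrom, pos))
            else:
                distinct_out.add((chrom, pos))
    out_driver = n_bp - in_driver
    genome_bp = sizes.total_bp
    rest_bp = genome_bp - driver_bp
    table = (
        (in_driver, driver_bp - len(distinct_in)),
        (out_driver, rest_bp - len(distinct_out)),
    )
    odds, p = _fisher_greater(table)
    return BreakpointEnrichmentResult(table, odds, p, mode="gene-level")


def breakpoint_length_corrected_enrichment(
    cohort: SampleSegmentSet,
    annotation: list[GeneRecord],
    driver_set: set[str],
) -> BreakpointEnrichmentResult:
    """Driver enrichment among genes with above-median breakpoint *rate*.

    Per gene, rate = breakpoints inside the gene / gene length; genes are
    dichotomized at the genome-wide median rate (strictly above vs not) and
    crossed with driver membership; one-sided Fisher (greater).
    """
    drivers_present = {g.symbol for g in annotation} & driver_set
    if not drivers_present:
        raise InputError("driver set does not intersect the annotation")
    bps = breakpoints(cohort)
    if sum(len(v) for v in bps.values()) == 0:
        raise InputError("empty breakpoint multiset")

    rates = np.empty(len(annotation))
    is_driver = np.empty(len(annotation), dtype=bool)
    for i, g in enumerate(annotation):
        positions = bps.get(g.chrom, [])
        count = bisect_right(positions, g.interval.end - 1) - bisect_left(
            positions, g.interval.start
        )
        rates[i] = count / g.length
        is_driver[i] = g.symbol in driver_set
    above = rates > np.median(rates)
    # rows: driver vs non-driver; columns: above-median rate vs not
    table = (
        (int(np.sum(above & is_driver)), int(np.sum(~above & is_driver))),
        (int(np.sum(above & ~is_driver)), int(np.sum(~above & ~is_driver))),
    )
    odds, p = _fisher_greater(table)
    return BreakpointEnrichmentResult(table, odds, p, mode="length-corrected")
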