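"""Permutation null, empirical p-values and Benjamini-Yekutieli FDR.

The null hypothesis is that deletion placement carries no gene-level
preference: the positions of *collective* segments are shuffled uniformly
within their chromosome, preserving each segment's chromosome, length and
sample count. Shuffled segments may overlap one another (rejection
sampling for non-overlap would bias placement on crowded chromosomes),
and the collective partition is not re-derived after placement, so the
null preserves the observed segment-length distribution. Gene scores are
recomputed on each placement with the same formula, giving a per-gene
background distribution.

Empirical p-values use the add-one estimator ``(1 + #{null >= obs}) /
(1 + n)`` (ties count as exceedances), so p is never 0 and never smaller
than ``1/(n+1)``. Because the Benjamini-Yekutieli adjustment multiplies by
``m * c(m) / rank``, discovery at level alpha requires roughly
``n + 1 >= m * c(m) / (alpha * k)`` permutations for k expected
discoveries among m genes; a warning is logged when the configured count
cannot resolve any discovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ChromosomeSizes, ConfigError, GeneRecord, InputError
from .scoring import score_all_genes
from .track import CollectiveTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the shuffling null.

    n_permutations : number of within-chromosome shuffles (>= 1).
    seed : seed for the placement RNG; fixes the whole analysis.
    alpha : FDR level applied to BY-adjusted p-values.
    """

    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PermutationConfig":
        known = {"n_permutations", "seed", "alpha"}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PermutationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        return cls.from_mapping(data)


@dataclass
class TrackPlacement:
    """One shuffled placement: per chromosome (starts, lengths, counts)."""

    chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def signature(self) -> list[tuple[str, int, int]]:
        """Multiset of (chrom, length, sample_count), sorted."""
        out = []
        for chrom, (starts, lengths, counts) in self.chrom_data.items():
            out.extend(
                (chrom, int(l), int(s)) for l, s in zip(lengths, counts)
            )
        return sorted(out)


def shuffle_track(
    track: CollectiveTrack, sizes: ChromosomeSizes, rng: np.random.Generator
) -> TrackPlacement:
    """Place every collective segment uniformly within its chromosome.

    Each segment's start is drawn independently and uniformly from
    ``{0, ..., chrom_len - L_i}``; lengths and sample counts ride along.
    The input track is not modified.
    """
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in track.chroms():
        starts, ends, counts = track.arrays(chrom)
        if starts.size == 0:
            continue
        if chrom not in sizes:
            raise InputError(f"chromosome {chrom!r} missing from sizes table")
        lengths = ends - starts
        hi = sizes[chrom] - lengths
        if np.any(hi < 0):
            raise InputError(
                f"collective segment longer than chromosome {chrom!r}"
            )
        new_starts = rng.integers(0, hi, endpoint=True)
        data[chrom] = (new_starts, lengths, counts)
    return TrackPlacement(chrom_data=data)


def placement_scores(
    annotation: list[GeneRecord], placement: TrackPlacement
) -> np.ndarray:
    """Gene scores against an (unsorted, possibly overlapping) placement."""
    scores = np.zeros(len(annotation))
    for i, gene in enumerate(annotation):
        if gene.chrom not in placement.chrom_data:
            continue
        starts, lengths, counts = placement.chrom_data[gene.chrom]
        mask = (starts < gene.interval.end) & (starts + lengths > gene.interval.start)
        if np.any(mask):
            scores[i] = float(
                np.sum(counts[mask] / (lengths[mask] + gene.length))
            )
    return scores


def null_distributions(
    annotation: list[GeneRecord],
    track: CollectiveTrack,
    sizes: ChromosomeSizes,
    config: PermutationConfig,
) -> np.ndarray:
    """Per-gene null score vectors, shape ``(len(annotation), n_permutations)``.

    Row order follows ``annotation``. Reproducible given ``config.seed``;
    permutation k is exactly the result of the k-th sequential
    :func:`shuffle_track` draw scored with the gene-score formula.
    """
    if not annotation:
        raise InputError("empty gene annotation")
    rng = np.random.default_rng(config.seed)
    n_genes = len(annotation)
    null = np.zeros((n_genes, config.n_permutations))

    # Pre-group genes by chromosome and precompute the per-term weights
    # S_i / (L_i + L_g), which do not depend on placement.
    per_chrom: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    for chrom in track.chroms():
        starts, ends, counts = track.arrays(chrom)
        if starts.size == 0:
            continue
        gidx = np.array(
            [i for i, g in enumerate(annotation) if g.chrom == chrom], dtype=np.int64
        )
        if gidx.size == 0:
            continue
        gstart = np.array([annotation[i].interval.start for i in gidx])
        gend = np.array([annotation[i].interval.end for i in gidx])
        glen = gend - gstart
        lengths = ends - starts
        weights = counts[None, :] / (lengths[None, :] + glen[:, None])
        per_chrom.append((chrom, gidx, gstart, gend, weights))

    for k in range(config.n_permutations):
        placement = shuffle_track(track, sizes, rng)
        for chrom, gidx, gstart, gend, weights in per_chrom:
            starts, lengths, _counts = placement.chrom_data[chrom]
            mask = (starts[None, :] < gend[:, None]) & (
                (starts + lengths)[None, :] > gstart[:, None]
            )
            null[gidx, k] = np.einsum("gs,gs->g", mask, weights)
    return null


def empirical_pvalue(
    observed: float, null: np.ndarray, n_permutations: int | None = None
) -> float:
    """Add-one empirical p-value; ties count as exceedances."""
    null = np.asarray(null)
    if n_permutations is not None and null.size != n_permutations:
        raise InputError(
            f"null vector has {null.size} entries, expected {n_permutations}"
        )
    n = null.size
    return float((1 + np.count_nonzero(null >= observed)) / (1 + n))


def adjust_benjamini_yekutieli(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment, valid under arbitrary
    dependence.

    With p-values sorted ascending, ``q_(i) = min(1, min_{j>=i}
    p_(j) * m * c(m) / j)`` where ``c(m) = sum_{k=1..m} 1/k``; results are
    mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("expected a non-empty 1-D vector of p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significance_table(
    annotation: list[GeneRecord],
    track: CollectiveTrack,
    sizes: ChromosomeSizes,
    config: PermutationConfig,
) -> pd.DataFrame:
    """Observed scores, permutation null, empirical and BY-adjusted p per gene.

    Genes on chromosomes without any collective segment score 0 against a
    null degenerate at 0, hence empirical p = 1. The BY correction is
    applied genome-wide across all scored genes as one family. Rows are
    ordered by (chrom, start, symbol); deterministic given the seed.
    """
    if not annotation:
        raise InputError("empty gene annotation")
    genes = sorted(
        annotation, key=lambda g: (g.chrom, g.interval.start, g.symbol)
    )
    min_adj = (1.0 / (config.n_permutations + 1)) * len(genes) * float(
        np.sum(1.0 / np.arange(1, len(genes) + 1))
    )
    if min_adj >= config.alpha:
        logger.warning(
            "permutation resolution: with n_permutations=%d and m=%d genes the "
            "smallest attainable BY-adjusted p at rank 1 is %.3g >= alpha=%g; "
            "no single gene can be flagged unless many share the minimal "
            "empirical p. Increase n_permutations for discovery.",
            config.n_permutations, len(genes), min_adj, config.alpha,
        )
    observed_map = score_all_genes(genes, track)
    observed = np.array([observed_map[g.symbol].score for g in genes])
    null = null_distributions(genes, track, sizes, config)
    exceed = np.count_nonzero(null >= observed[:, None], axis=1)
    n = config.n_permutations
    empirical = (1 + exceed) / (1 + n)
    adjusted = adjust_benjamini_yekutieli(empirical)
    return pd.DataFrame(
        {
            "symbol": [g.symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "score": observed,
            "n_null": n,
            "null_exceed": exceed,
            "empirical_p": empirical,
            "adjusted_p": adjusted,
            "significant": adjusted < config.alpha,
        }
    )


def by_resolution_requirement(m: int, alpha: float, k_discoveries: int = 1) -> int:
    """Smallest permutation count able to flag ``k_discoveries`` genes.

    Solves ``1/(n+1) * m * c(m) / k < alpha`` for n: genes at the add-one
    p floor are significant only when at least k of them share it.
    """
    c_m = math.fsum(1.0 / k for k in range(1, m + 1))
    return int(math.floor(m * c_m / (alpha * k_discoveries)))
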