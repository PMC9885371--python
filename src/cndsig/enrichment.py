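"""Downstream gene-set enrichment, pathway matrices, clustering and
2-D embedding of genome-wide significance profiles.

Significant genes from a run are tested against named gene sets (driver
catalogues, pathways) with a one-sided Fisher exact test whose universe is
the set of genes scored in the analysis: the question is selection among
tested genes, not among all genes a collection happens to mention.

Across several analyses, per-pathway log10 p-values are min-max
standardized to [0, 1] (0 marks the lowest p) and clustered with average
linkage on Euclidean distances; a small canonical-pathway variant keeps
the raw p-values and clusters pathways only. Genome-wide per-gene p-value
vectors ("significance profiles") are embedded in two dimensions with
UMAP to compare cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core import InputError


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's 2x2 against the significant/background split."""

    name: str
    n_sig_in_set: int
    n_sig_not_in_set: int
    n_nonsig_in_set: int
    n_nonsig_not_in_set: int
    odds_ratio: float
    pvalue: float

    @property
    def universe_size(self) -> int:
        return (
            self.n_sig_in_set
            + self.n_sig_not_in_set
            + self.n_nonsig_in_set
            + self.n_nonsig_not_in_set
        )


def set_enrichment(
    sig: set[str], universe: set[str], gene_set: set[str], name: str = ""
) -> EnrichmentRow:
    """One-sided (greater) Fisher exact test for over-representation of
    ``sig`` inside ``gene_set``, both intersected with ``universe`` first."""
    if not universe:
        raise InputError("empty universe")
    if not sig <= universe:
        raise InputError("significant genes must be a subset of the universe")
    in_set = gene_set & universe
    a = len(sig & in_set)
    b = len(sig) - a
    c = len(in_set) - a
    d = len(universe) - a - b - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentRow(
        name=name,
        n_sig_in_set=a,
        n_sig_not_in_set=b,
        n_nonsig_in_set=c,
        n_nonsig_not_in_set=d,
        odds_ratio=float(res.statistic),
        pvalue=float(res.pvalue),
    )


def enrichment_table(
    sig: set[str], universe: set[str], gene_sets: Mapping[str, set[str]]
) -> pd.DataFrame:
    rows = [
        set_enrichment(sig, universe, members, name=name)
        for name, members in gene_sets.items()
    ]
    return pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        ["pvalue", "name"], kind="mergesort", ignore_index=True
    )


def _pvalue_of(entry) -> float:
    return entry.pvalue if isinstance(entry, EnrichmentRow) else float(entry)


def pathway_matrix(
    analyses: Sequence[tuple[str, Mapping[str, object]]],
) -> pd.DataFrame:
    """Analyses x pathways matrix of standardized log10 Fisher p-values.

    Per pathway column, ``s = (log10 p - min) / (max - min)`` so the lowest
    p maps to 0; constant columns are set to 0 by convention. Input entries
    may be raw p-values or :class:`EnrichmentRow` objects. Pathways are
    restricted to those shared by every analysis.
    """
    if len(analyses) < 2:
        raise InputError("pathway standardization needs >= 2 analyses")
    shared = set(analyses[0][1])
    for _aid, rows in analyses[1:]:
        shared &= set(rows)
    if not shared:
        raise InputError("analyses share no pathway")
    cols = sorted(shared)
    ids = [aid for aid, _rows in analyses]
    logp = np.array(
        [[math.log10(_pvalue_of(rows[c])) for c in cols] for _aid, rows in analyses]
    )
    lo = logp.min(axis=0)
    hi = logp.max(axis=0)
    span = hi - lo
    out = np.zeros_like(logp)
    nonconst = span > 0
    out[:, nonconst] = (logp[:, nonconst] - lo[nonconst]) / span[nonconst]
    return pd.DataFrame(out, index=ids, columns=cols)


def canonical_pathway_matrix(
    analyses: Sequence[tuple[str, Mapping[str, object]]],
) -> pd.DataFrame:
    """Analyses x pathways matrix of raw one-sided Fisher p-values."""
    if not analyses:
        raise InputError("no analyses")
    shared = set(analyses[0][1])
    for _aid, rows in analyses[1:]:
        shared &= set(rows)
    if not shared:
        raise InputError("analyses share no pathway")
    cols = sorted(shared)
    ids = [aid for aid, _rows in analyses]
    raw = np.array(
        [[_pvalue_of(rows[c]) for c in cols] for _aid, rows in analyses]
    )
    return pd.DataFrame(raw, index=ids, columns=cols)


def hierarchical_cluster(matrix, axis: str = "rows") -> dict:
    """UPGMA (average linkage, Euclidean) on rows, columns or both.

    Returns per clustered axis a dict with the scipy ``linkage`` matrix,
    the leaf ``order`` and ordered ``labels``. Deterministic: scipy breaks
    distance ties by the lowest cluster index.
    """
    if axis not in {"rows", "cols", "both"}:
        raise InputError("axis must be 'rows', 'cols' or 'both'")
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        row_labels = list(matrix.index)
        col_labels = list(matrix.columns)
    else:
        values = np.asarray(matrix, dtype=float)
        row_labels = list(range(values.shape[0]))
        col_labels = list(range(values.shape[1]))
    if not np.all(np.isfinite(values)):
        raise InputError("matrix contains NaN or infinite values")

    def _one(data, labels):
        if data.shape[0] < 2:
            raise InputError("need >= 2 items to cluster")
        Z = hierarchy.linkage(data, method="average", metric="euclidean")
        order = hierarchy.leaves_list(Z).tolist()
        return {"linkage": Z, "order": order, "labels": [labels[i] for i in order]}

    out = {}
    if axis in {"rows", "both"}:
        out["rows"] = _one(values, row_labels)
    if axis in {"cols", "both"}:
        out["cols"] = _one(values.T, col_labels)
    return out


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height):
        branch = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{branch:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{branch:g}"

    return render(tree, tree.dist) + ";"


@dataclass(frozen=True)
class SignificanceProfile:
    """Genome-wide per-gene p-values of one analysis."""

    analysis_id: str
    symbols: tuple[str, ...]
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.pvalues):
            raise InputError("profile symbol/p-value length mismatch")
        p = np.asarray(self.pvalues, dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise InputError("profile p-values must lie in (0, 1]")


def profile_from_results(
    results: pd.DataFrame, analysis_id: str, column: str = "empirical_p"
) -> SignificanceProfile:
    """Build a profile from a significance result table."""
    return SignificanceProfile(
        analysis_id=analysis_id,
        symbols=tuple(results["symbol"]),
        pvalues=results[column].to_numpy(dtype=float),
    )


def embed_profiles(
    profiles: Sequence[SignificanceProfile],
    n_neighbors: int = 5,
    min_dist: float = 0.1,
    seed: int = 0,
    transform: str = "none",
) -> pd.DataFrame:
    """2-D UMAP embedding of significance profiles.

    Profiles are aligned on their shared gene symbols (ordered as in the
    first profile). ``transform='log10'`` embeds -log10(p) instead of raw
    p-values, which amplifies the informative low-p tail. Deterministic
    given ``seed``. The returned frame records the parameters in
    ``DataFrame.attrs``.
    """
    if len(profiles) < 3:
        raise InputError("embedding needs >= 3 profiles")
    if transform not in {"none", "log10"}:
        raise InputError("transform must be 'none' or 'log10'")
    shared = set(profiles[0].symbols)
    for p in profiles[1:]:
        shared &= set(p.symbols)
    if not shared:
        raise InputError("profiles share no gene symbols")
    order = [s for s in profiles[0].symbols if s in shared]
    mat = np.empty((len(profiles), len(order)))
    for i, prof in enumerate(profiles):
        lookup = {s: j for j, s in enumerate(prof.symbols)}
        mat[i] = prof.pvalues[[lookup[s] for s in order]]
    if transform == "log10":
        mat = -np.log10(mat)

    import umap  # deferred: heavy numba-backed import

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(profiles) - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(mat)
    out = pd.DataFrame(
        {
            "analysis_id": [p.analysis_id for p in profiles],
            "umap1": coords[:, 0],
            "umap2": coords[:, 1],
        }
    )
    out.attrs.update(
        {
            "n_neighbors": min(n_neighbors, len(profiles) - 1),
            "min_dist": min_dist,
            "seed": seed,
            "transform": transform,
            "n_genes": len(order),
        }
    )
    return out
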