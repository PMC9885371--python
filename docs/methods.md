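# Methods

## Model

The unit of evidence is the *collective segment*: overlaying every
sample's deletion segments partitions each chromosome at every distinct
segment boundary, and each maximal run between consecutive breakpoints
with coverage ≥ 1 becomes one atom carrying its length `L_i` and sample
count `S_i`. Atoms are deliberately **not** merged when neighbors share
the same `S_i` but different covering sample sets: each atom is a separate
term of the score, and merging would change `L_i`. Per-sample segments are
normalized first (sorted, overlapping or book-ended intervals merged), so
a deletion split by the caller at an internal point counts once, a sample
can never count twice on one atom, and coverage equals the number of
covering samples. Conservation holds by construction:
`Σ S_i·L_i` over the track equals the total deleted bp summed over
samples, and this identity is asserted in tests on random cohorts against
naive per-bp counting.

The gene score `Score_g = Σ_i S_i/(L_i + L_g)` sums over atoms
intersecting the gene by ≥ 1 bp (any partial overlap counts). The
`1/(L_i + L_g)` penalty encodes the observed decay of gene-hit frequency
with segment size: long deletions hit many genes indiscriminately and are
discounted; short recurrent deletions on a gene dominate. Scores are in
1/bp and are only compared within one analysis, where units cancel.

### Null model

Under the null of no gene-level preference, collective segments are placed
independently and uniformly within their chromosome: start drawn from
`{0, …, chrom_len − L_i}`, chromosome, `L_i` and `S_i` preserved, overlaps
among shuffled segments permitted, and the collective partition is *not*
re-derived after placement (re-collapsing would change the null's
segment-length distribution). Shuffling spans the full assembly length of
the chromosome, not the deleted-region envelope. Scores are recomputed per
shuffle with the same formula; the per-gene empirical p-value is the
add-one estimator `(1 + #{null ≥ obs})/(1 + n)` with ties counted as
exceedances, so p ∈ [1/(n+1), 1] and the estimator is valid (never 0).
Genes on chromosomes without any collective segment have a degenerate null
at 0 and observed 0, hence p = 1.

Benjamini–Yekutieli adjustment is applied genome-wide across all scored
genes as one family: with ascending p-values,
`q_(i) = min(1, min_{j≥i} p_(j)·m·c(m)/j)`, `c(m) = Σ_{k=1..m} 1/k`. BY
rather than Benjamini–Hochberg because neighboring genes' scores share
atoms and are arbitrarily dependent. A gene is flagged when its adjusted
p is below α (default 0.05).

### Permutation resolution

The add-one floor and the BY factor interact: a gene can only be flagged
when `n + 1 ≥ m·c(m)/(α·k)`, where k is the number of genes sharing the
minimal p. For m = 200 genes at α = 0.05 and k = 5 this requires n ≥ 4703
permutations; the default n = 1000 is therefore a screening resolution,
and `significance_table` logs a warning whenever the configured count
cannot resolve any discovery. `by_resolution_requirement()` exposes the
bound programmatically. Raising n only sharpens the floor; it does not
change gene ranks (ranks are fixed by the observed scores and the null
ensemble).

## Diagnostics

*Gene-hit frequency (GHF)* of a collective segment is genes hit per 100 kb
of segment length. Each of the `S_i` covering samples contributes one
record (one "gene deletion event"), i.e. multiplicity weighting, not
`ghf × S_i`: the y-value stays genes/100 kb, which is what produces the
visible hyperbolic curves of discrete hit counts over segment size.
Summaries are per-100-kb-bin weighted quartiles up to 5 Mb plus the
weighted Spearman correlation of (length, ghf) on the expanded records;
a constant-ghf input has correlation 0 by convention, and all-equal
lengths are a degenerate-input error.

*Breakpoint enrichment.* Two one-sided Fisher tests ask whether segment
endpoints concentrate in a driver-gene footprint. The exact 2×2
construction is a documented convention of this package (emitted in output
metadata): gene-level rows are breakpoints inside vs outside the merged
driver footprint (half-open containment, `start ≤ p < end`, multiplicity
kept), and the contrast column counts footprint bp minus distinct
breakpoint positions, so cells cannot go negative. The length-corrected
mode removes the advantage long genes have at catching breakpoints by
dichotomizing per-gene breakpoint *rates* (count/`L_g`) at the genome-wide
median and crossing that with driver membership. With equal gene lengths
the correction is family-wise a no-op (tested).

## Downstream analyses

Gene-set enrichment uses the one-sided (greater) Fisher exact test with
the universe equal to the genes scored in the analysis — the question is
selection among tested genes, not among a collection's catalogue. Pathway
profiles across analyses are `log10 p` min–max standardized per pathway to
[0, 1] (0 at the lowest p; constant columns set to 0 since min–max is
undefined there) and clustered with average linkage on Euclidean
distances; a canonical-pathway variant keeps raw p-values and clusters
pathways only. Profile embedding consumes per-gene empirical p-values
(adjusted p is a monotone transform that only coarsens ties); a `-log10`
transform is offered because Euclidean distance on raw p is dominated by
the uninformative bulk near 1, while `-log10` amplifies the informative
low-p tail — the two-cluster recovery demonstration uses it.

## Synthetic cohorts

The generator emulates the regime the model targets: per sample, a
Poisson(2) number of background deletions per chromosome with lengths
uniform on 50 kb – 1 Mb placed uniformly, plus, for each of 5 planted
genes, a focal deletion in a `penetrance = 0.3` fraction of samples with
length uniform on [`L_g`, `L_g` + 100 kb] positioned to overlap the gene.
The overhang makes collective segments around planted genes short and
recurrent and realistically drags immediate neighbors along
(co-segregation). Default genome: one 30 Mb chromosome carrying 200
non-overlapping genes with log-uniform lengths on 5–200 kb, giving ~35%
genic occupancy — chosen so the expected gene footprint
(`(b−a)/ln(b/a)·200 ≈ 10.6 Mb`) packs with realistic spacing. Gene
placement draws inter-gene gaps uniformly from the free space (the
conditional-uniform law); packing is retried a bounded number of times and
errors if infeasible. Truth is recorded pre-normalization so merged
background+focal events stay attributable, and an `annotation_seed`
separate from the cohort seed lets many cohorts share one gene list for
profile comparisons.

What the synthetic cohorts do *not* model: amplifications, subclonality
and purity, chromothripsis-like hyper-segmentation, probe- or
platform-specific breakpoint bias, multi-chromosome karyotypes with
realistic size spectra, and real gene-density heterogeneity. Passing
recovery/calibration tests therefore demonstrates correctness of the
machinery under the stated generative assumptions, not performance on any
real cohort.

## Numerical and design notes

- Coordinates are 0-based half-open throughout; 1-based formats are
  converted on ingest. Chromosome names are taken verbatim.
- Deletion-state selection is explicit configuration (token set, or a
  numeric column with a user-set threshold); no log2 threshold is assumed.
- Ties: `null ≥ observed` counts as an exceedance; BY uses a stable
  mergesort so equal p-values keep input order; scipy's linkage breaks
  distance ties by lowest cluster index, making dendrograms deterministic.
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; fixed-seed runs are byte-identical end to end (asserted
  via the CLI in tests).
- Problem sizes in the test suite and acceptance script (cohorts of
  20–100 samples, 30–200 genes, 200–5000 permutations, 5–10 seeds) are the
  package's chosen demonstration scale: large enough that the binomial,
  chi-square and KS checks have power, small enough to iterate on quickly.

## Known limitations

- **Independent-placement null is mildly anti-conservative per gene.**
  Real collective segments tile covered regions contiguously; shuffling
  them independently destroys that adjacency, so observed scores have
  higher variance than the null and the empirical p distribution on
  background-only cohorts has fat tails (measured P(p ≤ 0.01) ≈ 0.03).
  The permutation machinery itself is exactly calibrated — when observed
  scores are drawn from the shuffle ensemble the p-values pass a one-sided
  KS test against uniform comfortably — so this is a property of the
  null's independence assumption, not of the implementation. In practice
  the BY factor `c(m)` absorbs the inflation: the realized
  background-cohort false-flag rate at α = 0.05 is 0 in all tested seeds.
  A block-shuffle preserving atom adjacency would tighten calibration at
  the cost of a different (and less interpretable) null and is left out
  deliberately.
- At screening resolution (n = 1000, m = 200) no single gene can clear the
  BY bar (floor ≈ 0.17); discovery claims need the resolution bound above.
- Breakpoint-enrichment 2×2 tables are conventions, not canonical objects;
  alternative constructions change absolute p-values (directions agree in
  all simulated settings tested).
- Copy-number gains are out of scope: gain and loss have different
  genomic mechanics, and the length-penalty logic is specific to deletion.
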