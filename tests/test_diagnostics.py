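import numpy as np
import pytest

from cndsig.core import ChromosomeSizes, InputError, SampleSegmentSet
from cndsig.diagnostics import (
    breakpoint_gene_enrichment,
    breakpoint_length_corrected_enrichment,
    ghf_records,
    ghf_summary,
)
from cndsig.track import build_collective_track
from conftest import gene, iv
from oracle_utils import hypergeom_tail_greater, rank_based_spearman
from test_scoring import make_track


class TestGhfRecords:
    def test_unit_normalization(self):
        track = make_track([("chr1", 0, 100_000, 1)])
        rec = ghf_records(track, [gene("A", "chr1", 10, 20)])
        assert rec.loc[0, "ghf"] == pytest.approx(1.0)
        assert rec.loc[0, "bin_index"] == 1  # length exactly 100 kb

    def test_multiple_genes_per_segment(self):
        track = make_track([("chr1", 0, 250_000, 2)])
        genes = [gene(f"G{i}", "chr1", i * 40_000 + 10, i * 40_000 + 30_000)
                 for i in range(5)]
        rec = ghf_records(track, genes)
        assert rec.loc[0, "n_genes_hit"] == 5
        assert rec.loc[0, "ghf"] == pytest.approx(5 / 2.5)
        assert rec.loc[0, "sample_count"] == 2

    def test_zero_hit_segment_retained(self):
        track = make_track([("chr1", 0, 50_000, 1)])
        rec = ghf_records(track, [gene("A", "chr2", 0, 100)])
        assert len(rec) == 1 and rec.loc[0, "ghf"] == 0.0

    def test_position_invariance(self):
        genes_a = [gene("A", "chr1", 10_000, 20_000)]
        genes_b = [gene("A", "chr1", 710_000, 720_000)]
        rec_a = ghf_records(make_track([("chr1", 0, 100_000, 3)]), genes_a)
        rec_b = ghf_records(make_track([("chr1", 700_000, 800_000, 3)]), genes_b)
        assert rec_a.loc[0, "ghf"] == rec_b.loc[0, "ghf"]


class TestGhfSummary:
    def test_perfect_monotone_decay(self):
        track = make_track(
            [("chr1", i * 1_000_000, i * 1_000_000 + (i + 1) * 100_000, 1)
             for i in range(5)]
        )
        genes = [gene("A", "chr1", 0, 50_000)]  # only first segment hits it
        rec = ghf_records(track, genes)
        rec["n_genes_hit"] = [5, 4, 3, 2, 1]
        rec["ghf"] = rec["n_genes_hit"] / (rec["length"] / 100_000)
        _bins, rho, _p = ghf_summary(rec)
        assert rho == pytest.approx(-1.0)

    def test_constant_ghf_gives_zero_correlation(self):
        rec = ghf_records(make_track(
            [("chr1", 0, 100_000, 1), ("chr1", 500_000, 700_000, 2)]
        ), [gene("A", "chr2", 0, 10)])
        _bins, rho, _p = ghf_summary(rec)
        assert rho == 0.0

    def test_degenerate_lengths_error(self):
        rec = ghf_records(make_track([("chr1", 0, 100_000, 1)]),
                          [gene("A", "chr1", 0, 10)])
        with pytest.raises(InputError):
            ghf_summary(rec)

    def test_matches_rank_based_reference(self, rng):
        """Weighted Spearman equals Pearson-on-midranks on the expanded set."""
        segs = []
        pos = 0
        for i in range(100):
            length = int(rng.integers(50_000, 2_000_000))
            segs.append(("chr1", pos, pos + length, int(rng.integers(1, 6))))
            pos += length + 1000
        track = make_track(segs)
        genes = [gene(f"G{i}", "chr1", int(s), int(s) + 20_000)
                 for i, s in enumerate(rng.integers(0, pos, size=400))]
        rec = ghf_records(track, genes)
        _bins, rho, _p = ghf_summary(rec)
        idx = np.repeat(np.arange(len(rec)), rec["sample_count"].to_numpy())
        expected = rank_based_spearman(
            rec["length"].to_numpy()[idx], rec["ghf"].to_numpy()[idx]
        )
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_bin_quartiles_weighted_by_sample_count(self):
        track = make_track(
            [("chr1", 0, 90_000, 3), ("chr1", 200_000, 250_000, 1)]
        )
        genes = [gene("A", "chr1", 10, 50_000), gene("B", "chr1", 210_000, 220_000)]
        rec = ghf_records(track, genes)
        bins, _rho, _p = ghf_summary(rec)
        bin0 = bins.set_index("bin_index").loc[0]
        assert bin0["n_events"] == 4  # 3 events for segment 1 + 1 for segment 2


def proportional_breakpoint_cohort(rng, annotation, sizes, n_bp=400):
    """Breakpoints placed uniformly on the genome (no driver preference)."""
    samples = {}
    chrom = "chr1"
    for i in range(n_bp // 2):
        start = int(rng.integers(0, sizes[chrom] - 2))
        end = int(rng.integers(start + 1, sizes[chrom]))
        samples.setdefault(f"S{i % 20}", []).append(iv(chrom, start, end))
    return SampleSegmentSet(samples)


class TestBreakpointEnrichment:
    def setup_method(self):
        self.sizes = ChromosomeSizes({"chr1": 1_000_000})
        self.genes = [gene(f"G{i}", "chr1", i * 10_000, i * 10_000 + 5_000)
                      for i in range(100)]
        self.drivers = {f"G{i}" for i in range(10)}

    def test_all_breakpoints_in_drivers_matches_hypergeometric_oracle(self):
        cohort = SampleSegmentSet(
            {"A": [iv("chr1", 1_000, 2_000)], "B": [iv("chr1", 11_000, 12_000)]}
        )
        res = breakpoint_gene_enrichment(cohort, self.genes, self.drivers, self.sizes)
        assert res.pvalue == pytest.approx(
            hypergeom_tail_greater(res.table), rel=1e-10
        )
        assert res.pvalue < 1e-4  # drivers cover 5% of genome, all 4 bps inside

    def test_proportional_placement_not_enriched(self, rng):
        pvals = []
        for _ in range(10):
            cohort = proportional_breakpoint_cohort(rng, self.genes, self.sizes)
            res = breakpoint_gene_enrichment(
                cohort, self.genes, self.drivers, self.sizes
            )
            pvals.append(res.pvalue)
        assert np.median(pvals) > 0.05

    def test_zero_breakpoints_in_drivers_p_one_ish(self):
        cohort = SampleSegmentSet({"A": [iv("chr1", 990_000, 990_500)]})
        res = breakpoint_gene_enrichment(cohort, self.genes, self.drivers, self.sizes)
        assert res.pvalue > 0.99

    def test_empty_breakpoints_error(self):
        with pytest.raises(InputError):
            breakpoint_gene_enrichment(
                SampleSegmentSet({"A": []}), self.genes, self.drivers, self.sizes
            )

    def test_driver_set_disjoint_from_annotation_errors(self):
        cohort = SampleSegmentSet({"A": [iv("chr1", 0, 10)]})
        with pytest.raises(InputError):
            breakpoint_gene_enrichment(cohort, self.genes, {"NOPE"}, self.sizes)


class TestLengthCorrectedEnrichment:
    def setup_method(self):
        self.sizes = ChromosomeSizes({"chr1": 10_000_000})
        self.genes = [gene(f"G{i}", "chr1", i * 100_000, i * 100_000 + 50_000)
                      for i in range(100)]
        self.drivers = {f"G{i}" for i in range(10)}

    def test_identical_rates_no_signal(self):
        # one breakpoint pair inside every gene: identical per-bp rates
        cohort = SampleSegmentSet(
            {"A": [iv("chr1", i * 100_000 + 10, i * 100_000 + 20)
                   for i in range(100)]}
        )
        res = breakpoint_length_corrected_enrichment(cohort, self.genes, self.drivers)
        assert res.pvalue >= 0.5

    def test_planted_driver_rate_is_detected(self, rng):
        pvals = []
        for rep in range(5):
            samples = {}
            k = 0
            for g in self.genes[:10]:  # drivers: 12 breakpoint pairs each
                for _ in range(12):
                    s = int(rng.integers(g.interval.start, g.interval.end - 1))
                    samples.setdefault(f"S{k % 30}", []).append(iv("chr1", s, s + 1))
                    k += 1
            for g in self.genes[10:]:  # background: one pair each
                s = int(rng.integers(g.interval.start, g.interval.end - 1))
                samples.setdefault(f"S{k % 30}", []).append(iv("chr1", s, s + 1))
                k += 1
            res = breakpoint_length_corrected_enrichment(
                SampleSegmentSet(samples), self.genes, self.drivers
            )
            pvals.append(res.pvalue)
            assert res.pvalue == pytest.approx(
                hypergeom_tail_greater(res.table), rel=1e-10
            )
        assert max(pvals) < 0.001

    def test_no_breakpoints_error(self):
        with pytest.raises(InputError):
            breakpoint_length_corrected_enrichment(
                SampleSegmentSet({"A": []}), self.genes, self.drivers
            )


class TestEqualLengthAnnotation:
    def test_both_modes_agree_in_direction_when_lengths_equal(self, rng):
        """With equal gene lengths the rate correction is a family-wise no-op:
        both modes point the same way on a driver-loaded cohort."""
        sizes = ChromosomeSizes({"chr1": 10_000_000})
        genes = [gene(f"G{i}", "chr1", i * 100_000, i * 100_000 + 10_000)
                 for i in range(80)]
        drivers = {f"G{i}" for i in range(8)}
        samples = {}
        k = 0
        for g in genes[:8]:
            for _ in range(10):
                s = int(rng.integers(g.interval.start, g.interval.end - 1))
                samples.setdefault(f"S{k % 15}", []).append(iv("chr1", s, s + 1))
                k += 1
        cohort = SampleSegmentSet(samples)
        a = breakpoint_gene_enrichment(cohort, genes, drivers, sizes)
        b = breakpoint_length_corrected_enrichment(cohort, genes, drivers)
        assert a.pvalue < 0.01 and b.pvalue < 0.01
        assert a.odds_ratio > 1 and b.odds_ratio > 1
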