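"""Windowed densities, hyper/hypo classification, region merging."""

import pytest

from varscape.io_formats import VariantRecord
from varscape.landscape import (
    INDEL_THRESHOLDS,
    SNP_THRESHOLDS,
    WindowDensity,
    chromosome_density_table,
    classify_window,
    merge_regions,
    window_counts,
)


def snp(pos, chrom="chr1"):
    return VariantRecord(chrom, pos, "A", "G")


class TestWindowCounts:
    def test_empty_chromosome_tiles_fully(self):
        windows = window_counts([], {"chr1": 300_000})
        assert [(w.start, w.end) for w in windows] == [
            (1, 100_000), (100_001, 200_000), (200_001, 300_000),
        ]
        assert all(w.snp_count == 0 for w in windows)

    def test_boundary_position_belongs_to_lower_window(self):
        windows = window_counts([snp(100_000), snp(100_001)], {"chr1": 300_000})
        assert [w.snp_count for w in windows] == [1, 1, 0]

    def test_trailing_partial_window_uses_true_length(self):
        windows = window_counts([snp(200_050)], {"chr1": 200_100})
        assert windows[-1].length == 100
        assert windows[-1].snp_per_kb == pytest.approx(10.0)

    def test_counts_partition_chromosome_total(self, small_sim):
        from varscape.filtering import filter_variants, passed_records

        _, (genome, models, records, truth) = small_sim
        passed = passed_records(filter_variants(records))
        windows = window_counts(passed, genome.lengths)
        assert sum(w.snp_count + w.indel_count for w in windows) == len(passed)

    def test_variant_beyond_chromosome_end_is_error(self):
        with pytest.raises(ValueError, match="beyond"):
            window_counts([snp(500)], {"chr1": 400})

    def test_shift_invariance(self):
        """Translating variants by a whole number of windows translates the
        non-empty windows identically."""
        base = [snp(p) for p in (5, 40_000, 99_999, 150_000)]
        shifted = [snp(p + 200_000) for p in (5, 40_000, 99_999, 150_000)]
        w1 = window_counts(base, {"chr1": 300_000})
        w2 = window_counts(shifted, {"chr1": 500_000})
        assert [w.snp_count for w in w1[:2]] == [w.snp_count for w in w2[2:4]]


class TestClassification:
    @pytest.mark.parametrize(
        "count, expected",
        [(600, "hyper"), (501, "hyper"), (500, "neither"), (10, "neither"),
         (9, "hypo"), (0, "hypo")],
    )
    def test_snp_thresholds_strict(self, count, expected):
        w = WindowDensity("c", 1, 100_000, count, 0)
        assert w.snp_class == expected

    @pytest.mark.parametrize(
        "count, expected",
        [(101, "hyper"), (100, "neither"), (1, "neither"), (0, "hypo")],
    )
    def test_indel_thresholds_strict(self, count, expected):
        w = WindowDensity("c", 1, 100_000, 0, count)
        assert w.indel_class == expected

    def test_classify_window_is_per_kb(self):
        assert classify_window(6.0, SNP_THRESHOLDS) == "hyper"
        assert classify_window(0.09, SNP_THRESHOLDS) == "hypo"
        assert classify_window(5.0, SNP_THRESHOLDS) == "neither"
        assert classify_window(0.005, INDEL_THRESHOLDS) == "hypo"


def mkwin(chrom, i, snps):
    return WindowDensity(chrom, i * 100_000 + 1, (i + 1) * 100_000, snps, 50)


class TestMergeRegions:
    def test_run_of_two_required(self):
        # classes: hypo hypo neither hypo -> one 2-window region, last stays single
        windows = [mkwin("c", 0, 0), mkwin("c", 1, 0), mkwin("c", 2, 300), mkwin("c", 3, 0)]
        regions = [r for r in merge_regions(windows) if r.variant_type == "SNP"]
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end, regions[0].n_windows) == (1, 200_000, 2)
        assert regions[0].region_class == "hypo"

    def test_all_neither_gives_no_regions(self):
        windows = [mkwin("c", i, 300) for i in range(4)]
        assert [r for r in merge_regions(windows) if r.variant_type == "SNP"] == []

    def test_maximal_merging_no_same_class_abutting(self):
        windows = [mkwin("c", i, 0) for i in range(5)]
        regions = [r for r in merge_regions(windows) if r.variant_type == "SNP"]
        assert len(regions) == 1 and regions[0].n_windows == 5

    def test_runs_do_not_cross_chromosomes(self):
        windows = [mkwin("a", 0, 0), mkwin("a", 1, 0), mkwin("b", 0, 0), mkwin("b", 1, 0)]
        regions = [r for r in merge_regions(windows) if r.variant_type == "SNP"]
        assert [r.chromosome for r in regions] == ["a", "b"]

    def test_merging_is_idempotent_on_window_relabel(self):
        windows = [mkwin("c", i, 0 if i < 3 else 700) for i in range(6)]
        first = merge_regions(windows)
        second = merge_regions(windows)
        assert first == second


class TestDesertRecovery:
    def test_planted_desert_and_hotspot_recovered(self, small_sim):
        from varscape.filtering import filter_variants, passed_records

        config, (genome, models, records, truth) = small_sim
        passed = passed_records(filter_variants(records))
        windows = window_counts(passed, genome.lengths)
        snp_regions = [r for r in merge_regions(windows) if r.variant_type == "SNP"]
        hypo = [r for r in snp_regions if r.region_class == "hypo"]
        hyper = [r for r in snp_regions if r.region_class == "hyper"]
        assert len(hypo) == 1 and len(hyper) == 1
        (chrom, a, b) = truth.deserts[0]
        assert hypo[0].chromosome == chrom
        assert hypo[0].start <= a and hypo[0].end >= b
        (chrom, a, b) = truth.hotspots[0]
        assert hyper[0].chromosome == chrom
        assert hyper[0].start <= a and hyper[0].end >= b


class TestChromosomeDensity:
    def test_density_per_100kb(self):
        records = [snp(i * 997 + 1) for i in range(1000)]
        table = chromosome_density_table(records, {"chr1": 1_000_000})
        row = table[table.chromosome == "chr1"].iloc[0]
        assert row.snps == 1000
        assert row.snp_density == pytest.approx(100.0)

    def test_zero_variants(self):
        table = chromosome_density_table([], {"chr1": 1_000_000})
        assert table.iloc[0].snp_density == 0.0

    def test_uniform_rate_matches_binomial_expectation(self, small_sim):
        """Background rate r per base gives density close to r x 100,000
        outside the planted desert/hotspot structure."""
        config, (genome, models, records, truth) = small_sim
        chrom = "chr1"
        lo, hi = 600_001, 1_000_000  # unstructured tail of chr1
        n = sum(1 for r in records if r.chromosome == chrom and lo <= r.position <= hi)
        expected = config.variant_rate * (hi - lo + 1)
        assert abs(n - expected) < 4 * expected**0.5 + 0.05 * expected
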