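"""The synthetic-data generator: determinism, valid gene structures,
planted-label correctness, and frequency targets."""

import numpy as np
import pytest
from Bio.Seq import Seq

from varscape.io_formats import write_fasta, write_gff, write_vcf
from varscape.synthetic import (
    GenePlant,
    SimulationConfig,
    generate_genome,
    make_ssrg_fixture,
    oracle_coding_effect,
    plant_variants,
    simulate,
)


class TestGenerateGenome:
    def test_deterministic_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chromosome_length=100_000, n_genes=4)
        for tag in ("a", "b"):
            genome, models, _ = generate_genome(cfg)
            write_fasta(genome, tmp_path / f"{tag}.fa")
            write_gff(models, tmp_path / f"{tag}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_every_cds_translates_cleanly(self):
        """Codon-table oracle: each CDS begins M, ends *, no internal stop."""
        cfg = SimulationConfig(seed=2, n_chromosomes=2, chromosome_length=200_000, n_genes=10)
        genome, models, _ = generate_genome(cfg)
        assert len(models) == 10
        for g in models:
            protein = str(Seq(g.spliced_cds(genome)).translate())
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=1, chromosome_length=200_000, n_genes=8)
        _, models, _ = generate_genome(cfg)
        spans = sorted(g.genic_span for g in models)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_no_genes_means_all_intergenic(self):
        cfg = SimulationConfig(seed=4, n_chromosomes=1, chromosome_length=100_000, n_genes=0)
        genome, models, records, truth = simulate(cfg)
        assert models == []
        assert all(t.region_class == "intergenic" for t in truth.per_variant.values())

    def test_too_many_genes_is_error(self):
        cfg = SimulationConfig(seed=5, n_chromosomes=1, chromosome_length=5_000, n_genes=10)
        with pytest.raises(ValueError, match="does not fit"):
            generate_genome(cfg)


class TestPlantVariants:
    def test_effect_mix_by_construction(self):
        cfg = SimulationConfig(
            seed=6, n_chromosomes=1, chromosome_length=100_000, n_genes=2,
            codons_range=(80, 80), variant_rate=0.0, adjacency_pair_count=0,
            gene_plants={
                "gene001": GenePlant(nonsynonymous=10, synonymous=2),
                "gene002": GenePlant(stop_gain=1, stop_loss=1, start_loss=1, start_gain=1),
            },
            default_gene_plant=None,
        )
        genome, models, records, truth = simulate(cfg)
        assert truth.per_gene["gene001"].ka == 10
        assert truth.per_gene["gene001"].ks == 2
        effects = sorted(
            t.coding_effect for t in truth.per_variant.values() if t.gene_id == "gene002"
        )
        assert effects == ["start-gain", "start-loss", "stop-gain", "stop-loss"]

    def test_desert_spans_contain_zero_records(self, small_sim):
        _, (genome, models, records, truth) = small_sim
        for chrom, a, b in truth.deserts:
            assert not any(
                r.chromosome == chrom and a <= r.position <= b for r in records
            )

    def test_fixed_seed_gives_identical_vcf_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_chromosomes=1, chromosome_length=150_000, n_genes=3)
        for tag in ("a", "b"):
            genome, _, records, _ = simulate(cfg)
            write_vcf(records, tmp_path / f"{tag}.vcf", contig_lengths=genome.lengths)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_every_record_has_exactly_one_truth_entry(self, small_sim):
        _, (genome, models, records, truth) = small_sim
        keys = [(r.chromosome, r.position, r.alt) for r in records]
        assert len(set(keys)) == len(keys)
        assert set(keys) == set(truth.per_variant)

    def test_frequency_targets_converge(self, small_sim):
        """Realized Ts/Tv and het fraction within 3 standard errors of the
        configured targets."""
        config, (genome, models, records, truth) = small_sim
        snps = [r for r in records if r.is_snp]
        n = len(snps)
        p_target = config.ts_tv_target / (1 + config.ts_tv_target)
        ts = sum(
            truth.per_variant[(r.chromosome, r.position, r.alt)].substitution_class
            == "transition"
            for r in snps
        )
        se = (p_target * (1 - p_target) / n) ** 0.5
        # gene-targeted plants pick specific alts, so compare over background
        bg = [r for r in snps if truth.per_variant[(r.chromosome, r.position, r.alt)].gene_id is None]
        ts_bg = sum(
            truth.per_variant[(r.chromosome, r.position, r.alt)].substitution_class
            == "transition"
            for r in bg
        )
        assert abs(ts_bg / len(bg) - p_target) < 3 * se * (n / len(bg)) ** 0.5
        het = sum(r.zygosity == "heterozygous" for r in records) / len(records)
        se_h = (config.het_fraction * (1 - config.het_fraction) / len(records)) ** 0.5
        assert abs(het - config.het_fraction) < 3 * se_h + 0.01

    def test_overlapping_desert_and_hotspot_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(
                desert_spans=[("chr1", 1000, 2000)],
                hotspot_spans=[("chr1", 1500, 2500, 2.0)],
            )


class TestOracle:
    @pytest.mark.parametrize(
        "cds, offset, alt, expected",
        [
            ("ATGGCTTAA", 5, "C", "synonymous"),      # GCT->GCC
            ("ATGTATTAA", 5, "A", "stop-gain"),       # TAT->TAA
            ("ATGGCTTAA", 0, "G", "start-loss"),
            ("ATGGCTTAA", 6, "C", "stop-loss"),       # TAA->CAA
            ("ATGGCTTAA", 3, "A", "non-synonymous"),  # GCT->ACT
        ],
    )
    def test_known_codon_changes(self, cds, offset, alt, expected):
        assert oracle_coding_effect(cds, offset, alt) == expected


class TestSsrgFixture:
    def test_per_gene_truth_counts_match_panel(self, ssrg):
        genome, models, records, truth = ssrg
        assert truth.per_gene["GBSSII"].ka == 10
        assert truth.per_gene["GBSSII"].ks == 2
        assert truth.per_gene["GBSSII"].non_coding_snps == 82
        zero = truth.per_gene["BEIIa"]
        assert (zero.ka, zero.ks, zero.non_coding_snps, zero.non_coding_indels) == (0, 0, 0, 0)
        assert sum(g.ka for g in truth.per_gene.values()) == 33
        assert sum(g.ks for g in truth.per_gene.values()) == 38

    def test_all_fixture_records_pass_filters(self, ssrg):
        from varscape.filtering import filter_variants

        genome, models, records, truth = ssrg
        assert all(o.passed for o in filter_variants(records))
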