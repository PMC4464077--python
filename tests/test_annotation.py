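"""Location, coding-effect and substitution classification."""

import pytest

from varscape.annotation import (
    annotate_variants,
    classify_coding_effect,
    classify_region,
    classify_substitution,
    summarize,
)
from varscape.io_formats import GeneModel, GenomeSequence, VariantRecord


def snp(pos, ref, alt, chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt, 30, 35.0, 65.0, 120.0, (1, 1))


@pytest.fixture
def toy_gene():
    """+ strand gene: 5'UTR [1,10], CDS [11,19]+[50,58] (ATG GCT TAT | GGA TGG TAA),
    3'UTR [59,70], intron [20,49]."""
    seq = (
        "CCCCCCCCCC"          # 1-10   5'UTR
        + "ATGGCTTAT"          # 11-19  CDS part 1
        + "GT" + "A" * 26 + "AG"  # 20-49  intron (GT...AG)
        + "GGATGGTAA"          # 50-58  CDS part 2
        + "CCCCCCCCCCCC"       # 59-70  3'UTR
    )
    genome = GenomeSequence({"chr1": seq})
    gene = GeneModel(
        "toy", "chr1", "+",
        exons=[(1, 19), (50, 70)],
        cds=[(11, 19), (50, 58)],
        utr5=[(1, 10)],
        utr3=[(59, 70)],
    )
    return genome, gene


class TestRegion:
    @pytest.mark.parametrize(
        "pos, expected",
        [
            (90, "intergenic"),   # beyond the genic span
            (5, "exon-5UTR"),
            (15, "exon-CDS"),
            (20, "splice-site"),  # first intron base
            (21, "splice-site"),
            (22, "intron"),
            (47, "intron"),
            (48, "splice-site"),  # last-but-one intron base
            (49, "splice-site"),
            (55, "exon-CDS"),
            (65, "exon-3UTR"),
        ],
    )
    def test_region_classes(self, toy_gene, pos, expected):
        genome, gene = toy_gene
        region, gene_id, multi = classify_region(snp(pos, "A", "G"), [gene])
        assert region == expected
        assert gene_id == (None if expected == "intergenic" else "toy")
        assert multi is False

    def test_overlapping_genes_first_by_start_wins(self, toy_gene):
        genome, gene = toy_gene
        other = GeneModel("other", "chr1", "+", exons=[(10, 60)], cds=[(20, 49)])
        region, gene_id, multi = classify_region(snp(15, "A", "G"), [other, gene])
        assert gene_id == "toy" and multi is True


class TestCodingEffect:
    def test_synonymous_third_position(self, toy_gene):
        genome, gene = toy_gene
        # codon 2 GCT -> GCC, both alanine
        effect, aa = classify_coding_effect(snp(19 - 3, "T", "C"), gene, genome)
        assert (effect, aa) == ("synonymous", (2, "A", "A"))

    def test_stop_gain(self, toy_gene):
        genome, gene = toy_gene
        # codon 3 TAT -> TAA
        effect, aa = classify_coding_effect(snp(19, "T", "A"), gene, genome)
        assert (effect, aa) == ("stop-gain", (3, "Y", "*"))

    def test_non_synonymous_across_intron(self, toy_gene):
        genome, gene = toy_gene
        # codon 4 GGA -> AGA (G->R), first base of second CDS interval
        effect, aa = classify_coding_effect(snp(50, "G", "A"), gene, genome)
        assert (effect, aa) == ("non-synonymous", (4, "G", "R"))

    def test_start_loss(self, toy_gene):
        genome, gene = toy_gene
        effect, _ = classify_coding_effect(snp(11, "A", "G"), gene, genome)
        assert effect == "start-loss"

    def test_stop_loss(self, toy_gene):
        genome, gene = toy_gene
        # codon 6 TAA -> CAA
        effect, aa = classify_coding_effect(snp(56, "T", "C"), gene, genome)
        assert (effect, aa) == ("stop-loss", (6, "*", "Q"))

    def test_stop_to_stop_is_synonymous(self, toy_gene):
        genome, gene = toy_gene
        # codon 6 TAA -> TAG, still a stop
        effect, aa = classify_coding_effect(snp(58, "A", "G"), gene, genome)
        assert (effect, aa) == ("synonymous", (6, "*", "*"))

    def test_utr5_snp_without_new_atg_is_none(self, toy_gene):
        genome, gene = toy_gene
        # all-C 5'UTR: no single change can complete an upstream ATG
        effect, _ = classify_coding_effect(snp(9, "C", "T"), gene, genome)
        assert effect == "none"

    def test_start_gain_detected(self):
        # UTR "CCCTGC": the SNP C->A at position 3 creates "CCATGC" with an
        # ATG starting upstream of the annotated start -> start-gain
        genome = GenomeSequence({"c": "CCCTGC" + "ATGTTTTAA"})
        gene = GeneModel("g", "c", "+", exons=[(1, 15)], cds=[(7, 15)])
        effect, _ = classify_coding_effect(snp(3, "C", "A", chrom="c"), gene, genome)
        assert effect == "start-gain"

    def test_indel_and_noncoding_return_none(self, toy_gene):
        genome, gene = toy_gene
        assert classify_coding_effect(snp(30, "A", "G"), gene, genome) == ("none", None)


class TestStrandSymmetry:
    def test_minus_strand_mirror_gives_identical_effects(self, toy_gene):
        """Reverse-complementing the locus and flipping the strand must
        yield the same coding effect for the mirrored SNP."""
        genome, gene = toy_gene
        from Bio.Seq import Seq

        L = len(genome.sequences["chr1"])
        rc = str(Seq(genome.sequences["chr1"]).reverse_complement())
        mirror_genome = GenomeSequence({"chr1": rc})

        def flip(iv):
            a, b = iv
            return (L - b + 1, L - a + 1)

        mirror = GeneModel(
            "toy", "chr1", "-",
            exons=[flip(iv) for iv in gene.exons],
            cds=[flip(iv) for iv in gene.cds],
            utr5=[flip(iv) for iv in gene.utr5],
            utr3=[flip(iv) for iv in gene.utr3],
        )
        comp = dict(zip("ACGT", "TGCA"))
        for pos in range(11, 59):
            if not gene.in_cds(pos):
                continue
            ref = genome.fetch("chr1", pos, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                fwd, aa_f = classify_coding_effect(snp(pos, ref, alt), gene, genome)
                m_pos = L - pos + 1
                rev, aa_r = classify_coding_effect(
                    snp(m_pos, comp[ref], comp[alt]), mirror, mirror_genome
                )
                assert (fwd, aa_f) == (rev, aa_r)


class TestSubstitution:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "G", "transition"), ("G", "A", "transition"),
            ("C", "T", "transition"), ("T", "C", "transition"),
            ("A", "C", "transversion"), ("A", "T", "transversion"),
            ("C", "G", "transversion"), ("G", "T", "transversion"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_substitution(snp(5, ref, alt)) == expected

    def test_indel_is_not_a_snp(self):
        assert classify_substitution(VariantRecord("c", 1, "AT", "A")) == "not-a-SNP"


class TestSummary:
    def test_ts_tv_and_histogram(self, toy_gene):
        genome, gene = toy_gene
        records = [
            snp(80, "A", "G"), snp(85, "C", "T"), snp(95, "A", "C"),
            VariantRecord("chr1", 100, "A", "AT", 30, 35.0, 65.0, 120.0, (1, 1)),
            VariantRecord("chr1", 105, "A", "AG", 30, 35.0, 65.0, 120.0, (0, 1)),
            VariantRecord("chr1", 110, "ATT", "A", 30, 35.0, 65.0, 120.0, (1, 1)),
        ]
        genome = GenomeSequence({"chr1": genome.sequences["chr1"] + "A" * 60})
        s = summarize(annotate_variants(records, [gene], genome))
        assert s.ts_tv_ratio == pytest.approx(2.0)
        assert s.indel_length_histogram == {1: 2, -2: 1}
        assert s.indel_length_range == (-2, 1)
        assert s.hom_het_ratio_indel == pytest.approx(2.0)

    def test_zero_transversions_is_undefined_not_infinity(self):
        genome = GenomeSequence({"c": "A" * 50})
        s = summarize(annotate_variants([snp(5, "A", "G", chrom="c")], [], genome))
        assert s.ts_tv_ratio is None

    def test_partition_genic_plus_intergenic(self, small_sim):
        from varscape.filtering import filter_variants, passed_records

        _, (genome, models, records, truth) = small_sim
        passed = passed_records(filter_variants(records))
        s = summarize(annotate_variants(passed, models, genome))
        assert s.genic + s.intergenic == len(passed)
        assert sum(s.effect_counts.values()) == len(passed)


def test_planted_labels_recovered_exactly(small_sim):
    """Every truth label is recovered, with no false classifications."""
    from varscape.filtering import filter_variants, passed_records

    _, (genome, models, records, truth) = small_sim
    passed = passed_records(filter_variants(records))
    for a in annotate_variants(passed, models, genome):
        t = truth.per_variant[(a.record.chromosome, a.record.position, a.record.alt)]
        assert a.region_class == t.region_class
        assert a.coding_effect == t.coding_effect
        assert a.substitution_class == t.substitution_class
        assert a.gene_id == t.gene_id
        assert a.zygosity == t.zygosity
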