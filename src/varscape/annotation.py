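"""Codon-level variant effect annotation against gene models.

Each passed variant is classified by genomic location (intergenic,
exon-CDS, exon-5UTR, exon-3UTR, intron, splice-site), by coding effect
(synonymous, non-synonymous, stop-gain, stop-loss, start-gain,
start-loss), by substitution class (transition vs transversion), by indel
length, and by zygosity.

Conventions: splice sites are the first and last 2 bases of each intron
(the canonical GT/AG donor/acceptor positions) and take precedence over
the intron class; a start-gain is a 5'UTR SNP that creates an ATG triplet
anywhere upstream of the annotated start in the spliced transcript;
translation uses the standard genetic code (NCBI table 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import GeneModel, GenomeSequence, VariantRecord

REGION_CLASSES = (
    "intergenic", "exon-CDS", "exon-5UTR", "exon-3UTR", "intron", "splice-site",
)
CODING_EFFECTS = (
    "none", "synonymous", "non-synonymous", "stop-gain", "stop-loss",
    "start-gain", "start-loss",
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TRANSITIONS = ({"A", "G"}, {"C", "T"})
SPLICE_SITE_WIDTH = 2


def translate_codon(codon: str) -> str:
    """Single-letter amino acid for a codon, '*' for a stop."""
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass(frozen=True)
class VariantAnnotation:
    record: VariantRecord
    region_class: str
    coding_effect: str
    substitution_class: str
    gene_id: str | None
    amino_acid_change: tuple[int, str, str] | None
    multi_gene: bool = False

    @property
    def indel_length(self) -> int:
        return self.record.indel_length

    @property
    def zygosity(self) -> str:
        return self.record.zygosity


# ---------------------------------------------------------------------------
# location
# ---------------------------------------------------------------------------


def classify_region(
    record: VariantRecord, gene_models: list[GeneModel]
) -> tuple[str, str | None, bool]:
    """Locate a variant: (region-class, gene-id or None, multi-gene flag).

    A position inside any genic span is genic, subdivided by the containing
    feature; splice-site beats intron.  When genic spans overlap, the first
    gene by (start, gene-id) wins and the multi-gene flag is set.
    """
    hits = [
        g for g in gene_models
        if g.chromosome == record.chromosome and g.contains(record.position)
    ]
    if not hits:
        return ("intergenic", None, False)
    hits.sort(key=lambda g: (g.genic_span[0], g.gene_id))
    gene = hits[0]
    return (_region_within_gene(record.position, gene), gene.gene_id, len(hits) > 1)


def _region_within_gene(pos: int, gene: GeneModel) -> str:
    if gene.in_cds(pos):
        return "exon-CDS"
    for a, b in gene.introns:
        if a <= pos <= b:
            w = SPLICE_SITE_WIDTH
            if pos - a < w or b - pos < w:
                return "splice-site"
            return "intron"
    utr5, utr3 = gene.utr_intervals()
    if any(a <= pos <= b for a, b in utr5):
        return "exon-5UTR"
    if any(a <= pos <= b for a, b in utr3):
        return "exon-3UTR"
    # exonic but neither CDS nor UTR (e.g. non-coding gene)
    return "exon-5UTR" if not gene.cds else "exon-3UTR"


# ---------------------------------------------------------------------------
# coding effect
# ---------------------------------------------------------------------------


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the spliced CDS, 5'->3'."""
    forward = 0
    for a, b in gene.cds:
        if a <= pos <= b:
            forward += pos - a
            break
        forward += b - a + 1
    else:
        raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")
    if gene.strand == "+":
        return forward
    return gene.cds_length - 1 - forward


def _transcript_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset within the spliced transcript, 5'->3'."""
    forward = 0
    for a, b in gene.exons:
        if a <= pos <= b:
            forward += pos - a
            break
        forward += b - a + 1
    else:
        raise ValueError(f"position {pos} not exonic in {gene.gene_id}")
    total = sum(b - a + 1 for a, b in gene.exons)
    return forward if gene.strand == "+" else total - 1 - forward


def classify_coding_effect(
    record: VariantRecord, gene: GeneModel, genome: GenomeSequence
) -> tuple[str, tuple[int, str, str] | None]:
    """Classify a SNP inside a gene by its codon change.

    For CDS SNPs the containing codon is located in the spliced,
    strand-oriented CDS and both alleles translated: non-stop -> stop is a
    stop-gain, stop -> non-stop a stop-loss, any change destroying the
    initiator ATG a start-loss, an unchanged amino acid synonymous, else
    non-synonymous.  A 5'UTR SNP that creates an ATG upstream of the start
    is a start-gain.  Everything else returns ("none", None).
    """
    if not record.is_snp:
        return ("none", None)
    pos = record.position
    if gene.in_cds(pos):
        offset = _cds_offset(gene, pos)
        codon_index = offset // 3
        cds = gene.spliced_cds(genome)
        codon = cds[codon_index * 3 : codon_index * 3 + 3]
        within = offset % 3
        alt_base = record.alt
        if gene.strand == "-":
            alt_base = alt_base.translate(_COMPLEMENT)
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        ref_aa = translate_codon(codon)
        alt_aa = translate_codon(alt_codon)
        aa_change = (codon_index + 1, ref_aa, alt_aa)
        if codon_index == 0 and alt_codon != "ATG":
            return ("start-loss", aa_change)
        if ref_aa != "*" and alt_aa == "*":
            return ("stop-gain", aa_change)
        if ref_aa == "*" and alt_aa != "*":
            return ("stop-loss", aa_change)
        if ref_aa == alt_aa:
            return ("synonymous", aa_change)
        return ("non-synonymous", aa_change)
    if _region_within_gene(pos, gene) == "exon-5UTR" and gene.cds:
        if _creates_upstream_atg(record, gene, genome):
            return ("start-gain", None)
    return ("none", None)


def _creates_upstream_atg(
    record: VariantRecord, gene: GeneModel, genome: GenomeSequence
) -> bool:
    transcript = gene.spliced_transcript(genome)
    t_off = _transcript_offset(gene, record.position)
    cds_start = _transcript_offset(
        gene, gene.cds[0][0] if gene.strand == "+" else gene.cds[-1][1]
    )
    alt_base = record.alt
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    mutant = transcript[:t_off] + alt_base + transcript[t_off + 1 :]
    for start in range(max(0, t_off - 2), t_off + 1):
        if start >= cds_start or start + 3 > len(mutant):
            continue
        if mutant[start : start + 3] == "ATG" and transcript[start : start + 3] != "ATG":
            return True
    return False


# ---------------------------------------------------------------------------
# substitution class
# ---------------------------------------------------------------------------


def classify_substitution(record: VariantRecord) -> str:
    """Transition (A<->G, C<->T) vs transversion; InDels are not-a-SNP."""
    if not record.is_snp:
        return "not-a-SNP"
    pair = {record.ref, record.alt}
    return "transition" if pair in _TRANSITIONS else "transversion"


# ---------------------------------------------------------------------------
# driver + summary
# ---------------------------------------------------------------------------


def annotate_variants(
    records: list[VariantRecord],
    gene_models: list[GeneModel],
    genome: GenomeSequence,
) -> list[VariantAnnotation]:
    """Full per-variant classification bundle for a list of passed records."""
    by_id = {g.gene_id: g for g in gene_models}
    out = []
    for r in records:
        region, gene_id, multi = classify_region(r, gene_models)
        effect, aa = ("none", None)
        if gene_id is not None and r.is_snp:
            effect, aa = classify_coding_effect(r, by_id[gene_id], genome)
        out.append(
            VariantAnnotation(
                record=r,
                region_class=region,
                coding_effect=effect,
                substitution_class=classify_substitution(r),
                gene_id=gene_id,
                amino_acid_change=aa,
                multi_gene=multi,
            )
        )
    return out


@dataclass
class AnnotationSummary:
    """Global and per-chromosome tallies over a set of annotations."""

    n_variants: int
    n_snps: int
    n_indels: int
    genic: int
    intergenic: int
    region_counts: Counter
    effect_counts: Counter
    ts_tv_ratio: float | None
    hom_het_ratio_snp: float | None
    hom_het_ratio_indel: float | None
    indel_length_histogram: Counter
    indel_length_range: tuple[int, int] | None
    per_gene_nonsyn: Counter
    per_gene_syn: Counter
    per_chromosome: pd.DataFrame


def _safe_ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def summarize(annotations: list[VariantAnnotation]) -> AnnotationSummary:
    """Tally region, effect, Ts/Tv, zygosity and indel-length statistics.

    Ratios with a zero denominator are reported as ``None`` (undefined),
    never infinity.  Records with unknown zygosity are excluded from the
    hom/het tallies.
    """
    snps = [a for a in annotations if a.record.is_snp]
    indels = [a for a in annotations if a.record.is_indel]
    ts = sum(a.substitution_class == "transition" for a in snps)
    tv = sum(a.substitution_class == "transversion" for a in snps)

    def hom_het(group):
        hom = sum(a.zygosity == "homozygous" for a in group)
        het = sum(a.zygosity == "heterozygous" for a in group)
        return _safe_ratio(hom, het)

    lengths = Counter(a.indel_length for a in indels)
    rows = []
    for chrom in sorted({a.record.chromosome for a in annotations}):
        sub = [a for a in annotations if a.record.chromosome == chrom]
        s = [a for a in sub if a.record.is_snp]
        c_ts = sum(a.substitution_class == "transition" for a in s)
        c_tv = sum(a.substitution_class == "transversion" for a in s)
        rows.append(
            {
                "chromosome": chrom,
                "snps": len(s),
                "indels": len(sub) - len(s),
                "genic": sum(a.region_class != "intergenic" for a in sub),
                "intergenic": sum(a.region_class == "intergenic" for a in sub),
                "ts_tv": _safe_ratio(c_ts, c_tv),
            }
        )
    return AnnotationSummary(
        n_variants=len(annotations),
        n_snps=len(snps),
        n_indels=len(indels),
        genic=sum(a.region_class != "intergenic" for a in annotations),
        intergenic=sum(a.region_class == "intergenic" for a in annotations),
        region_counts=Counter(a.region_class for a in annotations),
        effect_counts=Counter(a.coding_effect for a in annotations),
        ts_tv_ratio=_safe_ratio(ts, tv),
        hom_het_ratio_snp=hom_het(snps),
        hom_het_ratio_indel=hom_het(indels),
        indel_length_histogram=lengths,
        indel_length_range=(min(lengths), max(lengths)) if lengths else None,
        per_gene_nonsyn=Counter(
            a.gene_id for a in snps if a.coding_effect == "non-synonymous"
        ),
        per_gene_syn=Counter(
            a.gene_id for a in snps if a.coding_effect == "synonymous"
        ),
        per_chromosome=pd.DataFrame(rows),
    )


def annotations_table(annotations: list[VariantAnnotation]) -> pd.DataFrame:
    """Flat per-variant table (one row per annotated record)."""
    rows = []
    for a in annotations:
        aa = a.amino_acid_change
        rows.append(
            {
                "chrom": a.record.chromosome,
                "pos": a.record.position,
                "ref": a.record.ref,
                "alt": a.record.alt,
                "region_class": a.region_class,
                "gene": a.gene_id or ".",
                "effect": a.coding_effect,
                "aa_change": f"{aa[1]}{aa[0]}{aa[2]}" if aa else ".",
                "substitution": a.substitution_class,
                "indel_len": a.indel_length,
                "zygosity": a.zygosity,
            }
        )
    return pd.DataFrame(rows)
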