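"""Readers and writers for the three standard formats the pipeline touches.

All internal coordinates are 1-based closed intervals, matching GFF3 and
VCF conventions; the BED convention (0-based half-open) is applied only at
write time.  FASTA parsing goes through :mod:`Bio.SeqIO`, VCF through
:mod:`pysam`, and GFF3 through :mod:`gffutils`.

The VCF dialect is fixed: read depth from INFO/DP, mapping quality from
INFO/MQ, base quality from INFO/BQ, variant quality from the QUAL column,
and genotype from the first sample's GT.  Missing numeric fields default to
0 so that they fail downstream quality filters rather than erroring.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

Interval = tuple[int, int]


class FormatError(ValueError):
    """Malformed input file or record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Chromosome-id -> uppercase nucleotide string; the coordinate frame."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            bad = next((i for i, c in enumerate(seq) if c not in VALID_BASES), None)
            if bad is not None:
                raise FormatError(
                    f"illegal character {seq[bad]!r} in {chrom} at position {bad + 1}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence on the 1-based closed interval [start, end]."""
        return self.sequences[chrom][start - 1 : end]


def _intervals_sorted_disjoint(ivals: list[Interval]) -> bool:
    return all(a[1] < b[0] for a, b in zip(ivals, ivals[1:]))


@dataclass
class GeneModel:
    """One mRNA's strand and exon/CDS/UTR structure.

    Intervals are 1-based closed and stored in ascending genomic order
    regardless of strand; on strand ``-`` the translated frame starts from
    the highest CDS coordinate.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        self.utr5 = sorted(tuple(u) for u in self.utr5)
        self.utr3 = sorted(tuple(u) for u in self.utr3)
        if not self.exons:
            raise FormatError(f"{self.gene_id}: gene without exons")
        if not _intervals_sorted_disjoint(self.exons):
            raise FormatError(f"{self.gene_id}: exons overlap")
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise FormatError(f"{self.gene_id}: CDS {c} outside every exon")
        if self.cds:
            total = self.cds_length
            if total % 3 != 0:
                raise FormatError(
                    f"{self.gene_id}: CDS length {total} not a multiple of 3"
                )

    @property
    def genic_span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def genic_length_kb(self) -> float:
        lo, hi = self.genic_span
        return (hi - lo + 1) / 1000

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def introns(self) -> list[Interval]:
        return [
            (a[1] + 1, b[0] - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    def contains(self, pos: int) -> bool:
        lo, hi = self.genic_span
        return lo <= pos <= hi

    def in_cds(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.cds)

    def utr_intervals(self) -> tuple[list[Interval], list[Interval]]:
        """Explicit UTRs if annotated, else exonic sequence outside the CDS
        split at the CDS bounds by strand."""
        if self.utr5 or self.utr3:
            return self.utr5, self.utr3
        if not self.cds:
            return [], []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        before, after = [], []
        for a, b in self.exons:
            if a < cds_lo:
                before.append((a, min(b, cds_lo - 1)))
            if b > cds_hi:
                after.append((max(a, cds_hi + 1), b))
        return (before, after) if self.strand == "+" else (after, before)

    def spliced_cds(self, genome: GenomeSequence) -> str:
        """CDS nucleotides 5'->3' (reverse-complemented on strand -)."""
        seq = "".join(genome.fetch(self.chromosome, a, b) for a, b in self.cds)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq

    def spliced_transcript(self, genome: GenomeSequence) -> str:
        """Exonic nucleotides 5'->3' (mRNA without introns)."""
        seq = "".join(genome.fetch(self.chromosome, a, b) for a, b in self.exons)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq


@dataclass(frozen=True)
class VariantRecord:
    """One called variant; the unit flowing through filter -> annotation.

    ``genotype`` is the unordered pair of allele indices from the first
    sample's GT, or ``None`` when the call has no genotype.  Quality fields
    missing from the source default to 0 so they fail the filters.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    depth: int = 0
    base_quality: float = 0.0
    mapping_quality: float = 0.0
    variant_quality: float = 0.0
    genotype: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise FormatError(f"{self.chromosome}:{self.position}: empty allele")
        if self.is_snp and self.ref == self.alt:
            raise FormatError(
                f"{self.chromosome}:{self.position}: alt equals ref"
            )
        if len(self.ref) == len(self.alt) > 1:
            raise FormatError(
                f"{self.chromosome}:{self.position}: multi-nucleotide "
                "substitutions are not supported"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def indel_length(self) -> int:
        """Signed length change; 0 for SNPs."""
        return len(self.alt) - len(self.ref)

    @property
    def zygosity(self) -> str:
        if self.genotype is None:
            return "unknown"
        a, b = self.genotype
        return "homozygous" if a == b else "heterozygous"

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased, multi-line records concatenated, and the
    header token before the first whitespace becomes the chromosome id.
    Duplicate ids and non-ACGTN characters are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate chromosome id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR"}


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3: one :class:`GeneModel` per mRNA.

    Parent attributes are resolved through :mod:`gffutils`; intervals come
    out sorted ascending by start regardless of strand.  A CDS outside any
    exon, or a CDS total length not divisible by 3, is a hard error naming
    the gene.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(mrna):
            ival = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(ival)
            elif child.featuretype == "CDS":
                cds.append(ival)
            elif child.featuretype in _UTR5_TYPES:
                utr5.append(ival)
            elif child.featuretype in _UTR3_TYPES:
                utr3.append(ival)
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


def write_gff(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""

    def line(chrom, ftype, start, end, strand, attrs):
        return "\t".join(
            [chrom, "varscape", ftype, str(start), str(end), ".", strand, ".", attrs]
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chromosome, g.genic_span[0])):
            lo, hi = m.genic_span
            gid = m.gene_id
            fh.write(line(m.chromosome, "gene", lo, hi, m.strand, f"ID=gene:{gid}") + "\n")
            fh.write(
                line(m.chromosome, "mRNA", lo, hi, m.strand, f"ID={gid};Parent=gene:{gid}")
                + "\n"
            )
            for ftype, ivals in (
                ("exon", m.exons),
                ("CDS", m.cds),
                ("five_prime_UTR", m.utr5),
                ("three_prime_UTR", m.utr3),
            ):
                for a, b in ivals:
                    fh.write(
                        line(m.chromosome, ftype, a, b, m.strand, f"Parent={gid}") + "\n"
                    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _info_number(row, key, default=0.0):
    try:
        value = row.info.get(key)
    except (KeyError, ValueError):  # key absent from the header
        return default
    if value is None:
        return default
    if isinstance(value, tuple):
        value = value[0]
    return value


def read_vcf(
    path: str | os.PathLike, genome: GenomeSequence | None = None
) -> list[VariantRecord]:
    """Read a VCF into sorted :class:`VariantRecord` objects.

    Multi-allelic rows are split into one record per alt allele, each
    retaining the row's quality fields.  A missing QUAL is treated as 0
    (fails the variant-quality filter); a missing GT leaves zygosity
    unknown.  If a genome is supplied, a REF mismatch is a hard error.
    """
    records: list[VariantRecord] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(os.fspath(path)) as vcf:
            samples = list(vcf.header.samples)
            for row in vcf:
                genotype = None
                if samples:
                    gt = row.samples[samples[0]].get("GT")
                    if gt is not None and None not in gt and len(gt) == 2:
                        genotype = tuple(sorted(gt))
                if genome is not None:
                    expected = genome.fetch(
                        row.chrom, row.pos, row.pos + len(row.ref) - 1
                    )
                    if expected != row.ref:
                        raise FormatError(
                            f"{row.chrom}:{row.pos}: REF {row.ref!r} does not match "
                            f"genome {expected!r}"
                        )
                for alt in row.alts or ():
                    records.append(
                        VariantRecord(
                            chromosome=row.chrom,
                            position=row.pos,
                            ref=row.ref,
                            alt=alt,
                            depth=int(_info_number(row, "DP", 0)),
                            base_quality=float(_info_number(row, "BQ", 0.0)),
                            mapping_quality=float(_info_number(row, "MQ", 0.0)),
                            variant_quality=float(row.qual) if row.qual is not None else 0.0,
                            genotype=genotype,
                        )
                    )
    finally:
        pysam.set_verbosity(save)
    records.sort(key=lambda r: r.sort_key)
    return records


def write_vcf(
    records: list[VariantRecord],
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as VCF v4.2 (dialect: INFO DP/MQ/BQ, QUAL, FORMAT GT).

    Records must be sorted by (chromosome, position); the output
    round-trips losslessly through :func:`read_vcf`.
    """
    keys = [r.sort_key for r in records]
    if keys != sorted(keys):
        raise FormatError("write_vcf requires records sorted by (chromosome, position)")
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_meta("INFO", items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Read depth at the site")])
    header.add_meta("INFO", items=[("ID", "MQ"), ("Number", 1), ("Type", "Float"),
                                   ("Description", "RMS mapping quality")])
    header.add_meta("INFO", items=[("ID", "BQ"), ("Number", 1), ("Type", "Float"),
                                   ("Description", "Mean base quality at the site")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"),
                                     ("Description", "Genotype")])
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.chromosome] = max(
                contig_lengths.get(r.chromosome, 0), r.position + len(r.ref)
            )
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_sample("sample1")
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            row = out.new_record(
                contig=r.chromosome,
                start=r.position - 1,
                stop=r.position - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
                qual=r.variant_quality,
            )
            row.info["DP"] = r.depth
            row.info["MQ"] = r.mapping_quality
            row.info["BQ"] = r.base_quality
            row.samples["sample1"]["GT"] = r.genotype if r.genotype is not None else (None, None)
            out.write(row)


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def write_bed(
    regions: list[tuple[str, int, int, str]], path: str | os.PathLike
) -> None:
    """Write (chrom, start, end, name) 1-based closed intervals as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t0\t.\n")


def write_tsv(table, path: str | os.PathLike) -> None:
    """Write a pandas DataFrame as a TSV without the index."""
    table.to_csv(os.fspath(path), sep="\t", index=False)
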