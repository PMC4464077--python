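"""Truth-labelled synthetic genomes, gene models and variant sets.

The generator emulates the statistical structure of a deeply resequenced
rice genome at toy scale: multi-chromosome sequences carrying
intron/exon gene structures, a variant set with controlled coding-effect
composition, controlled zygosity and transition/transversion mix,
planted zero-variant stretches (SNP deserts) and high-density stretches
(hotspots), and per-record quality fields spanning both sides of the
filter thresholds.  Every emitted record carries a truth label, so the
full pipeline (filter -> annotate -> landscape -> selection) can be
checked for exact label recovery.

Planted coding effects are validated at planting time with an
independent rebuild-and-translate check, so truth labels are correct by
construction rather than by trusting the annotator.  All randomness
flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .io_formats import GeneModel, GenomeSequence, VariantRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"

SITE_CRITERIA = ("depth", "base-quality", "mapping-quality", "variant-quality")


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class GenePlant:
    """Per-gene planting plan: counts of each planted variant kind."""

    nonsynonymous: int = 0
    synonymous: int = 0
    stop_gain: int = 0
    stop_loss: int = 0
    start_loss: int = 0
    start_gain: int = 0
    intron_snps: int = 0
    splice_snps: int = 0
    utr5_snps: int = 0
    utr3_snps: int = 0
    noncoding_indels: int = 0
    coding_indels: int = 0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated genome.

    Defaults mirror the headline statistics of the real data: one variant
    per 297 bases genome-wide, an InDel fraction of 8.3%, a Ts/Tv target
    of 2.2 and a homozygous:heterozygous ratio of 27.4 (het fraction
    1/28.4).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 20
    exons_per_gene: int = 3
    codons_range: tuple[int, int] = (40, 80)
    intron_length_range: tuple[int, int] = (100, 200)
    utr_length_range: tuple[int, int] = (30, 60)
    gene_ids: list[str] | None = None
    variant_rate: float = 1 / 297
    indel_fraction: float = 0.083
    ts_tv_target: float = 2.2
    het_fraction: float = 1 / 28.4
    fail_fraction: float = 0.05
    adjacency_pair_count: int = 3
    gene_plants: dict[str, GenePlant] = field(default_factory=dict)
    #: plan applied to every gene without an explicit gene_plants entry
    default_gene_plant: GenePlant | None = field(
        default_factory=lambda: GenePlant(
            nonsynonymous=2,
            synonymous=2,
            intron_snps=4,
            splice_snps=1,
            utr5_snps=1,
            utr3_snps=1,
            noncoding_indels=1,
        )
    )
    desert_spans: list[tuple[str, int, int]] = field(default_factory=list)
    hotspot_spans: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = [(c, a, b) for c, a, b in self.desert_spans]
        spans += [(c, a, b) for c, a, b, _ in self.hotspot_spans]
        spans.sort()
        for (c1, a1, b1), (c2, a2, b2) in zip(spans, spans[1:]):
            if c1 == c2 and a2 <= b1:
                raise ValueError("desert and hotspot spans must not overlap")
        if any(
            v < 0
            for plant in self.gene_plants.values()
            for v in vars(plant).values()
        ):
            raise ValueError("planted counts must be non-negative")


@dataclass(frozen=True)
class VariantTruth:
    passes: bool
    fail_reasons: frozenset[str]
    region_class: str
    coding_effect: str
    substitution_class: str
    zygosity: str
    gene_id: str | None = None


@dataclass
class GeneTruth:
    ka: int = 0
    ks: int = 0
    non_coding_snps: int = 0
    non_coding_indels: int = 0
    coding_indels: int = 0


@dataclass
class TruthTable:
    per_variant: dict[tuple[str, int, str], VariantTruth] = field(default_factory=dict)
    deserts: list[tuple[str, int, int]] = field(default_factory=list)
    hotspots: list[tuple[str, int, int]] = field(default_factory=list)
    per_gene: dict[str, GeneTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# planting-time effect oracle (independent of the annotator)
# ---------------------------------------------------------------------------


def oracle_coding_effect(cds: str, offset: int, alt: str) -> str:
    """Effect of a single-base change at ``offset`` of a spliced CDS,
    decided by rebuilding the mutant CDS and translating both strings."""
    mutant = cds[:offset] + alt + cds[offset + 1 :]
    if offset < 3 and mutant[:3] != "ATG":
        return "start-loss"
    codon_i = offset // 3
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = mutant[codon_i * 3 : codon_i * 3 + 3]
    if ref_codon not in _STOPS and alt_codon in _STOPS:
        return "stop-gain"
    if ref_codon in _STOPS and alt_codon not in _STOPS:
        return "stop-loss"
    ref_protein = str(Seq(cds).translate())
    alt_protein = str(Seq(mutant).translate())
    return "synonymous" if ref_protein == alt_protein else "non-synonymous"


def _creates_upstream_atg(transcript: str, cds_start: int, t_off: int, alt: str) -> bool:
    mutant = transcript[:t_off] + alt + transcript[t_off + 1 :]
    for s in range(max(0, t_off - 2), t_off + 1):
        if s < cds_start and s + 3 <= len(mutant):
            if mutant[s : s + 3] == "ATG" and transcript[s : s + 3] != "ATG":
                return True
    return False


def substitution_class(ref: str, alt: str) -> str:
    if len(ref) != 1 or len(alt) != 1:
        return "not-a-SNP"
    return "transition" if _TRANSITION_OF[ref] == alt else "transversion"


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


@dataclass
class _GeneLayout:
    """Bookkeeping linking a gene's transcript frame to the genome."""

    model: GeneModel
    span_start: int  # genomic start of the pre-mRNA span (1-based)
    pre_length: int
    exon_t: list[tuple[int, int]]  # transcript-offset ranges per exon chunk
    exon_p: list[tuple[int, int]]  # pre-mRNA-offset ranges per exon chunk
    utr5_len: int
    cds_seq: str

    def t_to_genomic(self, t: int) -> int:
        return _t_to_genomic(
            self.model.strand, self.span_start, self.pre_length,
            self.exon_t, self.exon_p, t,
        )


def _t_to_genomic(
    strand: str,
    span_start: int,
    pre_length: int,
    exon_t: list[tuple[int, int]],
    exon_p: list[tuple[int, int]],
    t: int,
) -> int:
    for (t0, t1), (p0, _) in zip(exon_t, exon_p):
        if t0 <= t <= t1:
            p = p0 + (t - t0)
            break
    else:
        raise ValueError("transcript offset outside exons")
    if strand == "+":
        return span_start + p
    return span_start + (pre_length - 1 - p)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop internal codons + a stop codon."""
    internal = []
    while len(internal) < n_codons - 2:
        codon = "".join(rng.choice(list(_BASES), 3))
        if codon not in _STOPS and codon != "ATG":
            internal.append(codon)
    return "ATG" + "".join(internal) + str(rng.choice(list(_STOPS)))


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    span_start: int,
    config: SimulationConfig,
) -> tuple[_GeneLayout, str]:
    """Design one gene; returns its layout and the genomic span sequence."""
    n_codons = int(rng.integers(config.codons_range[0], config.codons_range[1] + 1))
    u5 = int(rng.integers(*_plus1(config.utr_length_range)))
    u3 = int(rng.integers(*_plus1(config.utr_length_range)))
    cds = _random_cds(rng, n_codons)
    transcript = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
    T = len(transcript)
    n_exons = min(config.exons_per_gene, T)
    sizes = [T // n_exons] * n_exons
    for i in range(T % n_exons):
        sizes[i] += 1
    exon_t, t = [], 0
    for s in sizes:
        exon_t.append((t, t + s - 1))
        t += s
    introns = [
        _random_seq(rng, int(rng.integers(*_plus1(config.intron_length_range))))
        for _ in range(n_exons - 1)
    ]
    pre_parts, exon_p, p = [], [], 0
    for i, (t0, t1) in enumerate(exon_t):
        exon_p.append((p, p + (t1 - t0)))
        pre_parts.append(transcript[t0 : t1 + 1])
        p += t1 - t0 + 1
        if i < len(introns):
            pre_parts.append(introns[i])
            p += len(introns[i])
    pre = "".join(pre_parts)
    span_seq = pre if strand == "+" else str(Seq(pre).reverse_complement())

    def g_interval(t0: int, t1: int) -> tuple[int, int]:
        a = _t_to_genomic(strand, span_start, len(pre), exon_t, exon_p, t0)
        b = _t_to_genomic(strand, span_start, len(pre), exon_t, exon_p, t1)
        return (min(a, b), max(a, b))

    exons = [g_interval(t0, t1) for t0, t1 in exon_t]
    cds_iv, utr5_iv, utr3_iv = [], [], []
    for t0, t1 in exon_t:
        for lo, hi, bucket in (
            (u5, u5 + len(cds) - 1, cds_iv),
            (0, u5 - 1, utr5_iv),
            (u5 + len(cds), T - 1, utr3_iv),
        ):
            a, b = max(t0, lo), min(t1, hi)
            if a <= b:
                bucket.append(g_interval(a, b))
    model = GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=exons,
        cds=cds_iv,
        utr5=utr5_iv,
        utr3=utr3_iv,
    )
    layout = _GeneLayout(model, span_start, len(pre), exon_t, exon_p, u5, cds)
    return layout, span_seq


def _plus1(rng_range: tuple[int, int]) -> tuple[int, int]:
    return (rng_range[0], rng_range[1] + 1)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return rng.integers(0, 4, n).astype(np.uint8).choose(
        np.frombuffer(b"ACGT", dtype=np.uint8)
    ).tobytes().decode("ascii")


def _blocked_spans(config: SimulationConfig, chrom: str) -> list[tuple[int, int]]:
    spans = [(a, b) for c, a, b in config.desert_spans if c == chrom]
    spans += [(a, b) for c, a, b, _ in config.hotspot_spans if c == chrom]
    return sorted((a - 10, b + 10) for a, b in spans)


def _free_intervals(
    lo: int, hi: int, blocked: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """[lo, hi] minus the blocked spans, as sorted closed intervals."""
    free = []
    cursor = lo
    for a, b in blocked:
        if b < lo or a > hi:
            continue
        if a > cursor:
            free.append((cursor, min(a - 1, hi)))
        cursor = max(cursor, b + 1)
    if cursor <= hi:
        free.append((cursor, hi))
    return free


def _shift_layout(layout: _GeneLayout, delta: int) -> _GeneLayout:
    """Translate a gene layout (built at span_start=1) by ``delta`` bases."""
    m = layout.model
    sh = lambda ivals: [(a + delta, b + delta) for a, b in ivals]
    model = GeneModel(
        gene_id=m.gene_id,
        chromosome=m.chromosome,
        strand=m.strand,
        exons=sh(m.exons),
        cds=sh(m.cds),
        utr5=sh(m.utr5),
        utr3=sh(m.utr3),
    )
    return replace(layout, model=model, span_start=layout.span_start + delta)


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], list["_GeneLayout"]]:
    """Deterministically build chromosomes and non-overlapping genes.

    Every generated CDS starts with ATG, ends with a stop codon, has no
    internal stop and a length divisible by 3; gene spans avoid planted
    desert/hotspot spans.  Raises if the genes do not fit.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sequences = {c: list(_random_seq(rng, config.chromosome_length)) for c in chroms}
    gene_ids = config.gene_ids or [f"gene{i + 1:03d}" for i in range(config.n_genes)]
    if len(gene_ids) != config.n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, gid in enumerate(gene_ids):
        per_chrom[chroms[i % len(chroms)]].append(gid)
    layouts: list[_GeneLayout] = []
    for chrom in chroms:
        ids = per_chrom[chrom]
        if not ids:
            continue
        margin = min(5000, config.chromosome_length // 20)
        free = _free_intervals(
            margin + 1, config.chromosome_length - margin, _blocked_spans(config, chrom)
        )
        total_free = sum(b - a + 1 for a, b in free)
        stride = max(1, total_free // len(ids))
        cursor = free[0][0] if free else 1
        for gid in ids:
            strand = "+" if (len(layouts) % 2 == 0) else "-"
            layout, span_seq = _build_gene(rng, gid, chrom, strand, 1, config)
            for a, b in free:
                s = max(a, cursor)
                if s + layout.pre_length - 1 <= b:
                    start = s
                    break
            else:
                raise ValueError(f"gene {gid} does not fit in chromosome {chrom}")
            layout = _shift_layout(layout, start - 1)
            end = start + layout.pre_length - 1
            sequences[chrom][start - 1 : end] = list(span_seq)
            layouts.append(layout)
            cursor = max(start + layout.pre_length + 10, start + stride)
    genome = GenomeSequence({c: "".join(s) for c, s in sequences.items()})
    for layout in layouts:
        if layout.model.spliced_cds(genome) != layout.cds_seq:
            raise AssertionError(
                f"internal error: CDS mismatch for {layout.model.gene_id}"
            )
    return genome, [l.model for l in layouts], layouts


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------


class _Spacer:
    """Tracks occupied positions per chromosome, enforcing a minimum gap."""

    def __init__(self, min_gap: int = 5) -> None:
        self.min_gap = min_gap
        self.occupied: dict[str, set[int]] = {}

    def free(self, chrom: str, pos: int, width: int = 1) -> bool:
        occ = self.occupied.setdefault(chrom, set())
        return not any(
            p in occ
            for p in range(pos - self.min_gap + 1, pos + width + self.min_gap - 1)
        )

    def take(self, chrom: str, pos: int, width: int = 1) -> None:
        self.occupied.setdefault(chrom, set()).update(range(pos, pos + width))


def _passing_quality(rng: np.random.Generator) -> dict[str, float]:
    return {
        "depth": int(rng.integers(5, 76)),
        "base_quality": float(rng.integers(30, 46)),
        "mapping_quality": float(rng.integers(60, 71)),
        "variant_quality": float(rng.integers(90, 201)),
    }


def _failing_value(rng: np.random.Generator, criterion: str) -> float:
    if criterion == "depth":
        return int(rng.integers(0, 5)) if rng.random() < 0.5 else int(rng.integers(76, 121))
    if criterion == "base-quality":
        return float(rng.integers(0, 30))
    if criterion == "mapping-quality":
        return float(rng.integers(0, 60))
    return float(rng.integers(0, 90))  # variant-quality


class _Planter:
    def __init__(self, genome: GenomeSequence, config: SimulationConfig) -> None:
        self.genome = genome
        self.config = config
        self.rng = np.random.default_rng((config.seed, 1))
        self.spacer = _Spacer()
        self.records: list[VariantRecord] = []
        self.truth = TruthTable(
            deserts=list(config.desert_spans),
            hotspots=[(c, a, b) for c, a, b, _ in config.hotspot_spans],
        )

    # -- low-level emit ----------------------------------------------------

    def emit(
        self,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        region: str,
        effect: str,
        gene_id: str | None,
        fail_reasons: frozenset[str] = frozenset(),
        zygosity: str | None = None,
    ) -> VariantRecord:
        q = _passing_quality(self.rng)
        for reason in fail_reasons:
            if reason in ("depth",):
                q["depth"] = _failing_value(self.rng, reason)
            elif reason == "base-quality":
                q["base_quality"] = _failing_value(self.rng, reason)
            elif reason == "mapping-quality":
                q["mapping_quality"] = _failing_value(self.rng, reason)
            elif reason == "variant-quality":
                q["variant_quality"] = _failing_value(self.rng, reason)
        if zygosity is None:
            zygosity = (
                "heterozygous"
                if self.rng.random() < self.config.het_fraction
                else "homozygous"
            )
        gt = (0, 1) if zygosity == "heterozygous" else (1, 1)
        rec = VariantRecord(
            chromosome=chrom,
            position=pos,
            ref=ref,
            alt=alt,
            depth=int(q["depth"]),
            base_quality=q["base_quality"],
            mapping_quality=q["mapping_quality"],
            variant_quality=q["variant_quality"],
            genotype=gt,
        )
        self.records.append(rec)
        site_fail = frozenset(r for r in fail_reasons if r in SITE_CRITERIA)
        self.truth.per_variant[(chrom, pos, alt)] = VariantTruth(
            passes=not fail_reasons,
            fail_reasons=frozenset(fail_reasons),
            region_class=region,
            coding_effect=effect,
            substitution_class=substitution_class(ref, alt),
            zygosity=zygosity,
            gene_id=gene_id,
        )
        self.spacer.take(chrom, pos, len(ref))
        return rec

    # -- gene-targeted planting -------------------------------------------

    def plant_gene(self, layout: _GeneLayout, plant: GenePlant) -> None:
        gene = layout.model
        gt = self.truth.per_gene.setdefault(gene.gene_id, GeneTruth())
        for effect, count in (
            ("non-synonymous", plant.nonsynonymous),
            ("synonymous", plant.synonymous),
            ("stop-gain", plant.stop_gain),
            ("stop-loss", plant.stop_loss),
            ("start-loss", plant.start_loss),
        ):
            self._plant_cds_effect(layout, effect, count)
        gt.ka += plant.nonsynonymous
        gt.ks += plant.synonymous
        self._plant_start_gain(layout, plant.start_gain)
        for region, count in (
            ("intron", plant.intron_snps),
            ("splice-site", plant.splice_snps),
            ("exon-5UTR", plant.utr5_snps),
            ("exon-3UTR", plant.utr3_snps),
        ):
            self._plant_noncoding_snps(layout, region, count)
        gt.non_coding_snps += (
            plant.intron_snps + plant.splice_snps + plant.utr5_snps + plant.utr3_snps
        )
        self._plant_noncoding_indels(layout, plant.noncoding_indels)
        gt.non_coding_indels += plant.noncoding_indels
        self._plant_coding_indels(layout, plant.coding_indels)
        gt.coding_indels += plant.coding_indels

    def _plant_cds_effect(self, layout: _GeneLayout, effect: str, count: int) -> None:
        if count == 0:
            return
        gene, cds = layout.model, layout.cds_seq
        planted = 0
        offsets = list(range(len(cds)))
        self.rng.shuffle(offsets)
        for off in offsets:
            if planted == count:
                break
            pos = layout.t_to_genomic(layout.utr5_len + off)
            if not self.spacer.free(gene.chromosome, pos):
                continue
            alts = [b for b in _BASES if b != cds[off]]
            self.rng.shuffle(alts)
            for alt in alts:
                if oracle_coding_effect(cds, off, alt) == effect:
                    g_ref = self.genome.fetch(gene.chromosome, pos, pos)
                    g_alt = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
                    assert g_ref == (cds[off] if gene.strand == "+" else cds[off].translate(_COMPLEMENT))
                    self.emit(
                        gene.chromosome, pos, g_ref, g_alt,
                        "exon-CDS", effect, gene.gene_id,
                    )
                    planted += 1
                    break
        if planted < count:
            raise ValueError(
                f"{gene.gene_id}: could only plant {planted}/{count} {effect} SNPs"
            )

    def _plant_start_gain(self, layout: _GeneLayout, count: int) -> None:
        if count == 0:
            return
        gene = layout.model
        transcript = gene.spliced_transcript(self.genome)
        planted = 0
        offsets = list(range(layout.utr5_len))
        self.rng.shuffle(offsets)
        for t_off in offsets:
            if planted == count:
                break
            pos = layout.t_to_genomic(t_off)
            if not self.spacer.free(gene.chromosome, pos):
                continue
            ref_t = transcript[t_off]
            for alt in _BASES:
                if alt == ref_t:
                    continue
                if _creates_upstream_atg(transcript, layout.utr5_len, t_off, alt):
                    g_ref = self.genome.fetch(gene.chromosome, pos, pos)
                    g_alt = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
                    self.emit(
                        gene.chromosome, pos, g_ref, g_alt,
                        "exon-5UTR", "start-gain", gene.gene_id,
                    )
                    planted += 1
                    break
        if planted < count:
            raise ValueError(f"{gene.gene_id}: could not plant {count} start-gain SNPs")

    def _noncoding_positions(self, gene: GeneModel, region: str) -> list[int]:
        if region == "intron":
            ivals = [(a + 2, b - 2) for a, b in gene.introns if b - a + 1 > 4]
        elif region == "splice-site":
            ivals = []
            for a, b in gene.introns:
                ivals += [(a, a + 1), (b - 1, b)]
        elif region == "exon-5UTR":
            ivals = gene.utr5
        else:
            ivals = gene.utr3
        return [p for a, b in ivals for p in range(a, b + 1)]

    def _plant_noncoding_snps(self, layout: _GeneLayout, region: str, count: int) -> None:
        if count == 0:
            return
        gene = layout.model
        positions = self._noncoding_positions(gene, region)
        self.rng.shuffle(positions)
        transcript = gene.spliced_transcript(self.genome) if region == "exon-5UTR" else ""
        planted = 0
        for pos in positions:
            if planted == count:
                break
            if not self.spacer.free(gene.chromosome, pos):
                continue
            ref = self.genome.fetch(gene.chromosome, pos, pos)
            alt = self._choose_snp_alt(ref)
            if region == "exon-5UTR":
                # avoid accidentally creating an upstream ATG (a start-gain)
                t_off = _transcript_offset_of(layout, pos)
                alt_t = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
                if _creates_upstream_atg(transcript, layout.utr5_len, t_off, alt_t):
                    continue
            self.emit(gene.chromosome, pos, ref, alt, region, "none", gene.gene_id)
            planted += 1
        if planted < count:
            raise ValueError(
                f"{gene.gene_id}: could only plant {planted}/{count} {region} SNPs"
            )

    def _plant_noncoding_indels(self, layout: _GeneLayout, count: int) -> None:
        gene = layout.model
        positions = self._noncoding_positions(gene, "intron")
        interior = set(positions)
        self.rng.shuffle(positions)
        planted = 0
        for pos in positions:
            if planted == count:
                break
            # 1-bp deletion anchored at pos; keep it inside the intron interior
            if pos + 1 not in interior:
                continue
            if not self.spacer.free(gene.chromosome, pos, width=2):
                continue
            ref = self.genome.fetch(gene.chromosome, pos, pos + 1)
            self.emit(gene.chromosome, pos, ref, ref[0], "intron", "none", gene.gene_id)
            planted += 1
        if planted < count:
            raise ValueError(f"{gene.gene_id}: could only plant {planted}/{count} intron InDels")

    def _plant_coding_indels(self, layout: _GeneLayout, count: int) -> None:
        gene = layout.model
        planted = 0
        offsets = list(range(len(layout.cds_seq) - 1))
        self.rng.shuffle(offsets)
        for off in offsets:
            if planted == count:
                break
            pos = layout.t_to_genomic(layout.utr5_len + off)
            if not self.spacer.free(gene.chromosome, pos, width=2):
                continue
            if not gene.in_cds(pos + 1):
                continue
            ref = self.genome.fetch(gene.chromosome, pos, pos + 1)
            self.emit(gene.chromosome, pos, ref, ref[0], "exon-CDS", "none", gene.gene_id)
            planted += 1
        if planted < count:
            raise ValueError(f"{gene.gene_id}: could only plant {planted}/{count} coding InDels")

    # -- background planting ----------------------------------------------

    def _choose_snp_alt(self, ref: str) -> str:
        p_ts = self.config.ts_tv_target / (1 + self.config.ts_tv_target)
        if self.rng.random() < p_ts:
            return _TRANSITION_OF[ref]
        tv = [b for b in _BASES if b != ref and b != _TRANSITION_OF[ref]]
        return str(self.rng.choice(tv))

    def _background_record(self, chrom: str, pos: int, fail: frozenset[str]) -> None:
        genome_len = self.genome.lengths[chrom]
        if self.rng.random() < self.config.indel_fraction and pos + 3 < genome_len:
            if self.rng.random() < 0.5:  # insertion
                ref = self.genome.fetch(chrom, pos, pos)
                alt = ref + _random_seq(self.rng, int(self.rng.integers(1, 4)))
                width = 1
            else:  # deletion
                k = int(self.rng.integers(1, 4))
                ref = self.genome.fetch(chrom, pos, pos + k)
                alt = ref[0]
                width = k + 1
            self.spacer.take(chrom, pos, width)
            self.emit(chrom, pos, ref, alt, "intergenic", "none", None, fail)
        else:
            ref = self.genome.fetch(chrom, pos, pos)
            self.emit(chrom, pos, ref, self._choose_snp_alt(ref), "intergenic",
                      "none", None, fail)

    def plant_background(self, gene_models: list[GeneModel]) -> None:
        cfg = self.config
        if cfg.variant_rate <= 0:
            return
        genic: dict[str, list[tuple[int, int]]] = {}
        for g in gene_models:
            lo, hi = g.genic_span
            genic.setdefault(g.chromosome, []).append((lo - 5, hi + 5))
        for chrom, length in self.genome.lengths.items():
            blocked = sorted(
                genic.get(chrom, [])
                + [(a, b) for c, a, b in cfg.desert_spans if c == chrom]
                + [(a - 5, b + 5) for c, a, b, _ in cfg.hotspot_spans if c == chrom]
            )
            pos = 1 + int(self.rng.geometric(cfg.variant_rate))
            while pos <= length - 5:
                if not any(a <= pos <= b for a, b in blocked):
                    if self.spacer.free(chrom, pos, width=4):
                        fail: set[str] = set()
                        for crit in SITE_CRITERIA:
                            if self.rng.random() < cfg.fail_fraction:
                                fail.add(crit)
                        self._background_record(chrom, pos, frozenset(fail))
                pos += max(5, int(self.rng.geometric(cfg.variant_rate)))
        # hotspots: planted at rate x multiplier
        for chrom, a, b, mult in cfg.hotspot_spans:
            rate = min(cfg.variant_rate * mult, 0.12)
            spans = genic.get(chrom, [])
            pos = a + int(self.rng.geometric(rate))
            while pos <= b - 4:
                if not any(lo <= pos <= hi for lo, hi in spans):
                    if self.spacer.free(chrom, pos, width=4):
                        self._background_record(chrom, pos, frozenset())
                pos += max(5, int(self.rng.geometric(rate)))

    def plant_adjacency_pairs(self, gene_models: list[GeneModel]) -> None:
        """Pairs of otherwise-good records < 5 bp apart: both must fail the
        adjacency criterion."""
        cfg = self.config
        genic = {
            (g.chromosome, p)
            for g in gene_models
            for p in range(g.genic_span[0] - 10, g.genic_span[1] + 11)
        }
        chroms = sorted(self.genome.lengths)
        planted = 0
        attempts = 0
        while planted < cfg.adjacency_pair_count and attempts < 10_000:
            attempts += 1
            chrom = chroms[attempts % len(chroms)]
            length = self.genome.lengths[chrom]
            pos = int(self.rng.integers(10, length - 10))
            gap = int(self.rng.integers(1, 5))
            if (chrom, pos) in genic or (chrom, pos + gap) in genic:
                continue
            if any(a <= pos <= b or a <= pos + gap <= b for a, b in
                   [(a, b) for c, a, b in cfg.desert_spans if c == chrom]
                   + [(a, b) for c, a, b, _ in cfg.hotspot_spans if c == chrom]):
                continue
            if not (self.spacer.free(chrom, pos) and self.spacer.free(chrom, pos + gap)):
                continue
            for p in (pos, pos + gap):
                ref = self.genome.fetch(chrom, p, p)
                self.emit(chrom, p, ref, self._choose_snp_alt(ref), "intergenic",
                          "none", None, frozenset({"adjacency"}))
            planted += 1


def _transcript_offset_of(layout: _GeneLayout, pos: int) -> int:
    for (t0, t1), (p0, p1) in zip(layout.exon_t, layout.exon_p):
        p = pos - layout.span_start
        if layout.model.strand == "-":
            p = layout.pre_length - 1 - p
        if p0 <= p <= p1:
            return t0 + (p - p0)
    raise ValueError("position not exonic")


def plant_variants(
    genome: GenomeSequence,
    layouts: list[_GeneLayout],
    config: SimulationConfig,
) -> tuple[list[VariantRecord], TruthTable]:
    """Plant gene-targeted, background, hotspot and adjacency-pair variants.

    Returns records sorted by (chromosome, position) and a truth table
    with one entry per record; desert spans contain no records at all.
    """
    planter = _Planter(genome, config)
    by_id = {l.model.gene_id: l for l in layouts}
    for gid in config.gene_plants:
        if gid not in by_id:
            raise ValueError(f"gene_plants references unknown gene {gid!r}")
    for layout in layouts:
        plant = config.gene_plants.get(layout.model.gene_id, config.default_gene_plant)
        if plant is not None:
            planter.plant_gene(layout, plant)
    models = [l.model for l in layouts]
    planter.plant_background(models)
    planter.plant_adjacency_pairs(models)
    planter.records.sort(key=lambda r: r.sort_key)
    return planter.records, planter.truth


def simulate(config: SimulationConfig):
    """Generate a genome and its variant set in one call.

    Returns (genome, gene_models, records, truth).
    """
    genome, models, layouts = generate_genome(config)
    records, truth = plant_variants(genome, layouts, config)
    return genome, models, records, truth


# ---------------------------------------------------------------------------
# the 18-gene starch-synthesis panel fixture
# ---------------------------------------------------------------------------

#: Published per-gene counts for the starch-synthesis-related gene (SSRG)
#: panel: (symbol, non-coding SNPs, Ka, Ks, non-coding InDels, coding InDels).
SSRG_PANEL: list[tuple[str, int, int, int, int, int]] = [
    ("AGPS2b", 14, 0, 2, 1, 0),
    ("SPHOL", 9, 0, 1, 1, 0),
    ("GPT1", 9, 1, 2, 2, 0),
    ("GBSSI", 10, 0, 0, 4, 0),
    ("GBSSII", 82, 10, 2, 7, 0),
    ("SSI", 59, 2, 7, 7, 0),
    ("SSIIa", 16, 1, 1, 0, 0),
    ("SSIIb", 14, 3, 1, 3, 0),
    ("SSIIIa", 20, 3, 4, 2, 0),
    ("SSIIIb", 13, 4, 6, 3, 0),
    ("SSIVa", 11, 2, 1, 1, 0),
    ("SSIVb", 17, 0, 3, 0, 0),
    ("BEI", 9, 0, 2, 1, 0),
    ("BEIIa", 0, 0, 0, 0, 0),
    ("BEIIb", 23, 2, 3, 5, 0),
    ("ISA1", 9, 1, 2, 1, 0),
    ("ISA2", 1, 2, 1, 0, 0),
    ("PUL", 47, 2, 0, 3, 0),
]


def make_ssrg_fixture(
    seed: int = 0,
) -> tuple[GenomeSequence, list[GeneModel], list[VariantRecord], TruthTable]:
    """Synthetic 18-gene starch-synthesis panel with the published per-gene
    SNP/InDel composition planted exactly.

    Each panel gene carries its published number of non-coding SNPs
    (planted in introns), non-synonymous (Ka) and synonymous (Ks) coding
    SNPs, and non-coding/coding InDels; all records carry passing quality
    fields.  The gene structures themselves are synthetic stand-ins, not
    the real rice loci.
    """
    config = SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chromosome_length=60_000,
        n_genes=len(SSRG_PANEL),
        exons_per_gene=3,
        codons_range=(110, 110),
        intron_length_range=(520, 520),
        utr_length_range=(40, 40),
        gene_ids=[row[0] for row in SSRG_PANEL],
        variant_rate=0.0,
        adjacency_pair_count=0,
        gene_plants={
            symbol: GenePlant(
                nonsynonymous=ka,
                synonymous=ks,
                intron_snps=nc_snps,
                noncoding_indels=nc_indels,
                coding_indels=c_indels,
            )
            for symbol, nc_snps, ka, ks, nc_indels, c_indels in SSRG_PANEL
        },
    )
    return simulate(config)
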