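# Methods

This note records the conventions, parameter choices and assumptions
behind each stage of the pipeline, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinates and formats

All internal coordinates are 1-based closed intervals, matching GFF3 and
VCF; BED output converts at write time (start−1, half-open end). The VCF
dialect is fixed: depth from INFO/DP, mapping quality from INFO/MQ, base
quality from INFO/BQ, variant quality from the QUAL column, genotype from
the first sample's GT. Variant callers disagree on where these
annotations live; a single documented dialect keeps the filter semantics
unambiguous. Missing numeric fields default to 0 so they fail the
filters — conservative behaviour consistent with minimising false
positives. Multi-allelic rows are split into one record per alt allele,
each retaining the row's quality fields, so all counting rules operate on
a uniform unit. A record is a SNP iff both alleles have length 1;
otherwise it is an InDel with signed length len(alt) − len(ref).

## Quality filtering

Thresholds (all overridable via `FilterConfig`): depth in [5, 75], base
quality ≥ 30, mapping quality ≥ 60, variant quality ≥ 90, adjacent
variant distance ≥ 5 bp. Bounds are inclusive on their stated side —
depth exactly 5 or 75 passes. The adjacency criterion runs *after* the
four site criteria, over site-survivors only, so a rejected low-quality
neighbour cannot kill a good call; within the survivors, both members of
any same-chromosome pair closer than 5 bp are removed. Removing one
member only (keeping, say, the higher-quality one) would retain more
calls but admits alignment artefacts that typically produce clustered
errors; both-removal is the conservative choice. Distance is measured
between POS values regardless of allele length.

## Effect annotation

Region classes partition genic positions: exon-CDS, exon-5'UTR,
exon-3'UTR, intron, and splice-site, defined as the first and last 2
bases of each intron (the canonical GT/AG donor/acceptor dinucleotides)
with precedence over the intron class. Explicit UTR features are used
when the GFF3 provides them; otherwise UTRs are derived as exonic
sequence outside the CDS, split by strand. A variant overlapping several
genes is reported against the first gene by (start, gene-id) with a
multi-gene flag; one mRNA per gene is assumed (no alternative
transcripts).

Coding effects use the standard genetic code (NCBI table 1). The spliced
CDS is assembled in genomic order and reverse-complemented on the minus
strand; the codon containing the SNP is translated for both alleles.
Classification precedence: any change destroying the initiator ATG is a
start-loss; then non-stop→stop is stop-gain, stop→non-stop is stop-loss;
an unchanged amino acid (including stop→stop) is synonymous; everything
else non-synonymous. A start-gain is a 5'UTR SNP creating an ATG triplet
that begins upstream of the annotated start in the spliced transcript, at
any offset — reading frame is deliberately ignored, matching the
conventional "start gained" definition. CDS InDels are tallied as coding
InDels without frameshift/in-frame subclasses. Ts/Tv and
homozygous/heterozygous ratios with a zero denominator are reported as
undefined, never infinity.

## Density landscape

Windows of 100 kb (configurable) tile each chromosome; the trailing
partial window is kept and its density uses the true length — dropping it
would erase deserts at chromosome ends. Classification is per variant
type with strict inequalities: hyper if SNPs/kb > 5 or InDels/kb > 1,
hypo if SNPs/kb < 0.1 or InDels/kb < 0.01. Regions ("successive"
hyper/hypo stretches, i.e. hotspots and SNP deserts) are maximal runs of
at least 2 consecutive same-class windows; single hyper/hypo windows
remain visible in the window table but are not regions. Chromosome-wide
density tables divide the variant count by chromosome length / 100 kb;
this is a whole-length convention — masked or uncovered bases are not
excluded from the denominator.

## Selection (Ka/Ks)

Ka and Ks are raw counts of non-synonymous and synonymous coding SNPs per
gene, and Ka/Ks is their plain ratio — deliberately *not* a per-site rate
(no Nei–Gojobori site normalisation, no codon-model dN/dS). The ratio is
undefined when Ks = 0 and rendered "—". Start/stop gain/loss SNPs count
in neither Ka nor Ks and are tallied separately. Selection classes:
neutral iff Ka/Ks = 1 exactly, negative below, positive above. Display
ratios round half-away-from-zero to 1 decimal (so ΣKa/ΣKs = 33/38 = 0.868
prints as 0.9); full precision is kept internally.

## Outlier genes

Per-gene density = non-synonymous SNP count / genic span in kb, where the
genic span runs from first to last exon including introns and UTRs. Genes
with zero non-synonymous SNPs are excluded from the distribution — the
distribution of interest is over carrier genes. Quartiles use linear
interpolation between order statistics (numpy's default), the common
box-plot convention; other conventions (Tukey hinges, nearest-rank) shift
the fence slightly on small samples. The fence is one-sided,
Q3 + 1.5·IQR, because the density distribution is strongly right-skewed;
a gene is an outlier iff its density strictly exceeds the fence.

## Summary arithmetic

Two reporting conventions are fixed deliberately: average coverage across
chromosomes is the *unweighted* mean of per-chromosome percentages (the
base-weighted genome-wide fraction is a different, also defensible number
— for the bundled mapping table they differ: 82.8 vs 83.1), and the
genome-wide variant rate ("one variant per N bases") truncates the
quotient rather than rounding. Percentages round half-up to 1 decimal.
Mapping summaries are consumed as tables of per-chromosome (length,
covered bases, reads); BAM parsing is out of scope.

## Synthetic data

The generator emulates, at toy scale, the statistical structure of a
deeply resequenced rice genome. Defaults: 2 chromosomes × 1 Mb, 20 genes
of 40–80 codons across 3 exons, one variant per 297 bases, 8.3% InDels,
Ts/Tv target 2.2, heterozygous fraction 1/28.4 (hom:het 27.4), 5% of
background records planted to fail each site criterion, and a small
per-gene mix of coding and non-coding variants. These figures mirror the
headline statistics of the motivating study's call set, so that default
runs exercise the pipeline under realistic proportions; the scale keeps
the full pipeline under a few seconds.

Truth labels are correct by construction: coding effects are validated at
planting time by an independent rebuild-and-translate check; background
variants are confined to intergenic space outside planted deserts;
hotspot spans receive rate × multiplier variants; all planted positions
keep ≥ 5 bp apart except deliberate adjacency-failure pairs, so the
intended filter outcome of every record is known. All randomness flows
from one seeded `numpy` generator; identical seeds give byte-identical
FASTA/GFF3/VCF output.

The 18-gene starch-synthesis (SSRG) panel fixture plants a published
per-gene composition — non-coding SNPs, Ka, Ks, non-coding and coding
InDels per gene — into synthetic gene structures (110 codons, 3 exons,
520-bp introns, 40-bp UTRs, on a 60-kb chromosome). The gene structures
are synthetic stand-ins, not the real rice loci; only the per-gene counts
are real, which is exactly what the Ka/Ks arithmetic consumes.

What the generator does **not** emulate: read-level error processes and
genotype-likelihood noise, linkage and population structure, repetitive
sequence and mappability variation, GC/codon-usage bias, multi-allelic
sites, overlapping genes and alternative transcripts. Passing the
round-trip tests therefore shows the pipeline's bookkeeping and
classification logic are exact, not that the filter thresholds are
well-calibrated for any particular sequencing platform.

## Problem sizes in tests

The test suite runs the full pipeline on 2 × 1 Mb genomes (~7,000
variants), exhaustive annotator-vs-oracle comparison on 12 genes of ≤ 10
codons (all 3 alternative alleles at every CDS position, both strands),
and quantile-oracle comparison on all input sizes ≤ 20. These sizes give
exact, deterministic checks; the operations are linear in variant count
and scale to genome-sized inputs without algorithmic changes.

## Known limitations

* One transcript per gene; no handling of genes with non-canonical start
  or stop annotation (a CDS not beginning ATG is accepted as input, and
  any change in codon 1 away from ATG is still labelled start-loss).
* Multi-nucleotide substitutions (equal-length multi-base alleles) are
  rejected as input rather than decomposed into SNPs.
* The adjacency filter is pairwise on POS; a deletion spanning into the
  5-bp window of a neighbour is not treated specially.
* Chromosome-wide density denominators use full length, not covered
  length; with incomplete coverage the two differ.
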