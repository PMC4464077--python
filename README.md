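# varscape

Whole-genome variant landscape analysis for resequencing studies:
quality filtering of called variants, codon-level effect annotation
against gene models, windowed SNP/InDel density landscapes with
SNP-desert and hotspot calling, per-gene Ka/Ks selection classification,
and box-plot outlier detection of non-synonymous SNP density.

The package targets the analysis that follows read alignment and variant
calling in a cultivar-vs-reference resequencing study (the motivating
case is the indica rice cultivar Swarna resequenced against the
Nipponbare reference): given a reference FASTA, gene models (GFF3) and a
called VCF, it produces the filtered call set, per-variant annotations,
the density landscape, and gene-panel selection reports. A synthetic-data
generator plants truth-labelled variants into toy genomes so the whole
pipeline can be validated end to end without any external download.

## The methods in brief

* **Filtering.** A variant is kept iff (1) read depth ∈ [5, 75],
  (2) base quality ≥ 30, (3) mapping quality ≥ 60, (4) variant quality
  ≥ 90, and (5) the nearest other surviving variant on the chromosome is
  ≥ 5 bp away (both members of a closer pair are removed).
* **Effect annotation.** Each passed variant is located (intergenic,
  exon-CDS, exon-5'UTR, exon-3'UTR, intron, splice-site — the first/last
  2 bp of each intron) and each CDS SNP is classified by its codon change
  under the standard genetic code: synonymous, non-synonymous, stop-gain,
  stop-loss, start-loss, and start-gain for 5'UTR SNPs creating an
  upstream ATG. SNPs are also split into transitions (A↔G, C↔T) and
  transversions, and zygosity is read from the genotype.
* **Landscape.** SNP and InDel counts per 100-kb window; a window is
  hyper-varying if SNPs/kb > 5 (InDels/kb > 1) and hypo-varying if
  SNPs/kb < 0.1 (InDels/kb < 0.01); runs of ≥ 2 consecutive same-class
  windows merge into regions — SNP deserts and hotspots.
* **Selection.** Per gene, Ka = non-synonymous and Ks = synonymous coding
  SNP counts; Ka/Ks is the raw count ratio; a gene is under neutral
  (Ka/Ks = 1), negative (< 1) or positive (> 1) selection, undefined when
  Ks = 0.
* **Outliers.** Per-gene non-synonymous SNPs per kb of genic span; the
  five-number summary with linear-interpolation quartiles gives the upper
  Tukey fence Q3 + 1.5·IQR; genes strictly above it are outliers.

## Worked example

Build the bundled 18-gene starch-synthesis panel fixture (synthetic gene
structures carrying a published per-gene variant composition), run the
pipeline, and report three genes:

```python
from varscape import (make_ssrg_fixture, filter_variants, passed_records,
                      annotate_variants, panel_report)

genome, genes, records, truth = make_ssrg_fixture(seed=1)
passed = passed_records(filter_variants(records))
annotations = annotate_variants(passed, genes, genome)
table = panel_report(["GBSSII", "SSIIa", "PUL"], annotations)
print(table.to_string(index=False))
```

prints

```
         gene  non_coding_snps  ka  ks ka_ks selection  non_coding_indels  coding_indels
       GBSSII               82  10   2   5.0  positive                  7              0
        SSIIa               16   1   1   1.0   neutral                  0              0
          PUL               47   2   0     — undefined                  3              0
Total/average              145  13   3   4.3         .                 10              0
```

GBSSII (granule-bound starch synthase II) carries 10 non-synonymous and
2 synonymous coding SNPs, so its Ka/Ks count ratio is 5.0 — a positive
selection signal; SSIIa sits exactly at the neutral ratio of 1.0; PUL has
no synonymous SNPs, so its ratio is undefined ("—"). The totals row sums
counts and forms the aggregate ratio ΣKa/ΣKs.

The same stages are exposed as a CLI:

```bash
varscape simulate --seed 3 --out-dir sim/          # genome.fa, genes.gff3, variants.vcf, truth.tsv
varscape filter --vcf sim/variants.vcf --out passed.vcf --rejects rejects.tsv
varscape annotate --vcf passed.vcf --gff sim/genes.gff3 --fasta sim/genome.fa --out annotated.tsv
varscape landscape --vcf passed.vcf --fasta sim/genome.fa --out windows.tsv --regions regions.bed
varscape run --config run.yaml                     # the whole pipeline
```

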