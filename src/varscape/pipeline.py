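"""End-to-end pipeline: filter -> annotate -> landscape -> selection -> outliers.

`run_pipeline` ties the stages together from a :class:`RunConfig`, writes
every stage output (TSV/VCF/BED) into the output directory plus a run
manifest with per-stage counts, and is deterministic for identical inputs
and seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import annotate_variants, annotations_table, summarize
from .filtering import FilterConfig, filter_variants, passed_records
from .io_formats import read_fasta, read_gff, read_vcf, write_bed, write_tsv, write_vcf
from .landscape import (
    WINDOW_SIZE_DEFAULT,
    chromosome_density_table,
    merge_regions,
    window_counts,
    windows_table,
)
from .outliers import gene_density_table
from .report import variant_rate
from .selection import panel_report

logger = logging.getLogger("varscape")


@dataclass
class RunConfig:
    fasta: str
    gff: str
    vcf: str
    out_dir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = WINDOW_SIZE_DEFAULT
    panel: list[str] | None = None  # None = all genes
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)

    def validate_paths(self) -> None:
        for p in (self.fasta, self.gff, self.vcf):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) with
    per-stage record counts and internal-consistency checks.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)

    genome = read_fasta(config.fasta)
    genes = read_gff(config.gff)
    records = read_vcf(config.vcf, genome=genome)
    logger.info("loaded %d variants, %d genes", len(records), len(genes))

    outcomes = filter_variants(records, config.filter)
    passed = passed_records(outcomes)
    logger.info("filter: %d/%d passed", len(passed), len(records))
    write_vcf(passed, out / "passed.vcf", contig_lengths=genome.lengths)
    rejects = [
        {
            "chrom": o.record.chromosome,
            "pos": o.record.position,
            "alt": o.record.alt,
            "failed": ",".join(sorted(o.failed_criteria)),
        }
        for o in outcomes
        if not o.passed
    ]
    import pandas as pd

    write_tsv(pd.DataFrame(rejects, columns=["chrom", "pos", "alt", "failed"]),
              out / "rejects.tsv")

    annotations = annotate_variants(passed, genes, genome)
    write_tsv(annotations_table(annotations), out / "annotated.tsv")
    summary = summarize(annotations)

    windows = window_counts(passed, genome.lengths, config.window_size)
    write_tsv(windows_table(windows), out / "windows.tsv")
    regions = merge_regions(windows)
    write_bed(
        [
            (r.chromosome, r.start, r.end, f"{r.variant_type}_{r.region_class}")
            for r in regions
        ],
        out / "regions.bed",
    )
    write_tsv(chromosome_density_table(passed, genome.lengths), out / "density.tsv")

    panel = config.panel if config.panel is not None else [g.gene_id for g in genes]
    sel_table = panel_report(panel, annotations)
    write_tsv(sel_table, out / "panel_report.tsv")

    dens_table = gene_density_table(genes, annotations)
    write_tsv(dens_table, out / "gene_density.tsv")

    total_bases = sum(genome.lengths.values())
    n_windows_total = sum(w.snp_count + w.indel_count for w in windows)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "fasta": str(config.fasta),
            "gff": str(config.gff),
            "vcf": str(config.vcf),
            "window_size": config.window_size,
        },
        "counts": {
            "input_variants": len(records),
            "passed_variants": len(passed),
            "snps": summary.n_snps,
            "indels": summary.n_indels,
            "genic": summary.genic,
            "intergenic": summary.intergenic,
            "regions": len(regions),
            "outlier_genes": int(dens_table["outlier"].sum()) if len(dens_table) else 0,
        },
        "ts_tv_ratio": summary.ts_tv_ratio,
        "variant_rate_bases_per_variant": variant_rate(total_bases, len(passed))
        if passed
        else None,
        "consistency": {
            "genic_plus_intergenic_equals_passed": summary.genic + summary.intergenic
            == len(passed),
            "window_counts_equal_passed": n_windows_total == len(passed),
        },
    }
    if not all(manifest["consistency"].values()):
        raise AssertionError(f"internal consistency check failed: {manifest['consistency']}")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
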