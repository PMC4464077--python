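"""Windowed variant-density landscape: hyper/hypo windows, deserts, hotspots.

Densities of SNPs and InDels are computed in tiling windows (default
100 kb; the trailing window keeps its true, shorter length so deserts at
chromosome ends are not lost).  A window is hyper-varying if SNPs/kb > 5
or InDels/kb > 1 and hypo-varying if SNPs/kb < 0.1 or InDels/kb < 0.01 —
strict inequalities, classified separately per variant type.  Maximal runs
of two or more consecutive same-class windows are merged into "successive"
regions: SNP deserts (hypo) and hotspots (hyper).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import VariantRecord

#: density thresholds per kb: (hyper if >, hypo if <)
SNP_THRESHOLDS = (5.0, 0.1)
INDEL_THRESHOLDS = (1.0, 0.01)

WINDOW_SIZE_DEFAULT = 100_000
MIN_SUCCESSIVE_WINDOWS = 2


@dataclass
class WindowDensity:
    chromosome: str
    start: int  # 1-based closed interval [start, end]
    end: int
    snp_count: int
    indel_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def snp_per_kb(self) -> float:
        return self.snp_count / (self.length / 1000)

    @property
    def indel_per_kb(self) -> float:
        return self.indel_count / (self.length / 1000)

    @property
    def snp_class(self) -> str:
        return classify_window(self.snp_per_kb, SNP_THRESHOLDS)

    @property
    def indel_class(self) -> str:
        return classify_window(self.indel_per_kb, INDEL_THRESHOLDS)


@dataclass
class DensityRegion:
    chromosome: str
    start: int
    end: int
    n_windows: int
    total_count: int
    mean_density_per_kb: float
    region_class: str  # hyper | hypo
    variant_type: str  # SNP | InDel


def window_counts(
    records: list[VariantRecord],
    chromosome_lengths: dict[str, int],
    window_size: int = WINDOW_SIZE_DEFAULT,
) -> list[WindowDensity]:
    """Count SNPs and InDels per tiling window on every chromosome.

    A variant belongs to the window containing its POS; window counts
    partition each chromosome's total.  A variant beyond the chromosome
    end is a hard error.
    """
    counts: dict[str, list[list[int]]] = {}
    n_windows = {
        c: max(1, -(-length // window_size)) for c, length in chromosome_lengths.items()
    }
    for c, n in n_windows.items():
        counts[c] = [[0, 0] for _ in range(n)]
    for r in records:
        if r.chromosome not in chromosome_lengths:
            raise ValueError(f"variant on unknown chromosome {r.chromosome!r}")
        if r.position > chromosome_lengths[r.chromosome]:
            raise ValueError(
                f"variant at {r.chromosome}:{r.position} beyond chromosome end"
            )
        idx = (r.position - 1) // window_size
        counts[r.chromosome][idx][1 if r.is_indel else 0] += 1
    windows = []
    for chrom in chromosome_lengths:
        length = chromosome_lengths[chrom]
        for i in range(n_windows[chrom]):
            start = i * window_size + 1
            end = min((i + 1) * window_size, length)
            snp, indel = counts[chrom][i]
            windows.append(WindowDensity(chrom, start, end, snp, indel))
    return windows


def classify_window(density_per_kb: float, thresholds: tuple[float, float]) -> str:
    """hyper if density > upper, hypo if density < lower, else neither."""
    hyper, hypo = thresholds
    if density_per_kb > hyper:
        return "hyper"
    if density_per_kb < hypo:
        return "hypo"
    return "neither"


def merge_regions(
    windows: list[WindowDensity],
    min_windows: int = MIN_SUCCESSIVE_WINDOWS,
) -> list[DensityRegion]:
    """Merge maximal runs of >= ``min_windows`` consecutive same-class
    windows into successive hyper/hypo regions, separately for SNPs and
    InDels.  Single-window features remain visible in the window table but
    are not regions."""
    regions: list[DensityRegion] = []
    for variant_type, cls_of, count_of in (
        ("SNP", lambda w: w.snp_class, lambda w: w.snp_count),
        ("InDel", lambda w: w.indel_class, lambda w: w.indel_count),
    ):
        run: list[WindowDensity] = []

        def flush():
            if len(run) >= min_windows and cls_of(run[0]) in ("hyper", "hypo"):
                total = sum(count_of(w) for w in run)
                span_kb = sum(w.length for w in run) / 1000
                regions.append(
                    DensityRegion(
                        chromosome=run[0].chromosome,
                        start=run[0].start,
                        end=run[-1].end,
                        n_windows=len(run),
                        total_count=total,
                        mean_density_per_kb=total / span_kb,
                        region_class=cls_of(run[0]),
                        variant_type=variant_type,
                    )
                )

        for w in windows:
            if run and (w.chromosome != run[-1].chromosome or cls_of(w) != cls_of(run[-1])):
                flush()
                run = []
            run.append(w)
        flush()
        run = []
    return regions


def windows_table(windows: list[WindowDensity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "snp_count": [w.snp_count for w in windows],
            "indel_count": [w.indel_count for w in windows],
            "snp_per_kb": [w.snp_per_kb for w in windows],
            "indel_per_kb": [w.indel_per_kb for w in windows],
            "snp_class": [w.snp_class for w in windows],
            "indel_class": [w.indel_class for w in windows],
        }
    )


def chromosome_density_table(
    records: list[VariantRecord], chromosome_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome SNP/InDel counts and densities per 100 kb.

    Density = count / (chromosome length / 100,000), reported to 1
    decimal, with a Total/Average row using the whole-genome length.
    """
    rows = []
    for chrom, length in chromosome_lengths.items():
        snp = sum(r.chromosome == chrom and r.is_snp for r in records)
        indel = sum(r.chromosome == chrom and r.is_indel for r in records)
        rows.append(
            {
                "chromosome": chrom,
                "snps": snp,
                "snp_density": round(snp / (length / 100_000), 1),
                "indels": indel,
                "indel_density": round(indel / (length / 100_000), 1),
            }
        )
    total_len = sum(chromosome_lengths.values())
    tot_snp = sum(r["snps"] for r in rows)
    tot_indel = sum(r["indels"] for r in rows)
    rows.append(
        {
            "chromosome": "Total/Average",
            "snps": tot_snp,
            "snp_density": round(tot_snp / (total_len / 100_000), 1),
            "indels": tot_indel,
            "indel_density": round(tot_indel / (total_len / 100_000), 1),
        }
    )
    return pd.DataFrame(rows)
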