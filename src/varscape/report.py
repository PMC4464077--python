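"""Mapping/coverage summary arithmetic and the genome-wide variant rate.

These helpers reproduce the headline bookkeeping of a resequencing run:
per-chromosome coverage percentages of uniquely mapped reads, the mapped
and uniquely-mapped read percentages, and the "one variant for every N
bases" rate.  Two conventions matter and are fixed here: the average
coverage is the *unweighted* mean of per-chromosome percentages (not the
base-weighted genome-wide fraction), and the variant rate truncates the
bases-per-variant quotient to an integer.

Mapping summaries are consumed as tabular input (any aligner's stats);
BAM parsing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .selection import UNDEFINED, round_half_up

#: Published per-chromosome mapping summary for the Swarna resequencing
#: run against the Nipponbare (IRGSP-1.0) reference: chromosome,
#: reference length (bp), uniquely covered bases, uniquely mapped reads.
SWARNA_MAPPING_TABLE: list[tuple[str, int, int, int]] = [
    ("1", 43_270_923, 37_267_274, 3_446_257),
    ("2", 35_937_250, 31_252_011, 2_906_369),
    ("3", 36_413_819, 32_749_423, 3_037_514),
    ("4", 35_502_694, 28_162_153, 2_665_489),
    ("5", 29_958_434, 26_207_749, 2_463_462),
    ("6", 31_248_787, 25_988_755, 2_454_467),
    ("7", 29_697_621, 24_291_613, 2_262_245),
    ("8", 28_443_022, 23_369_142, 2_199_600),
    ("9", 23_012_720, 18_969_755, 1_792_075),
    ("10", 23_207_287, 19_040_419, 1_970_091),
    ("11", 29_021_106, 22_012_814, 2_035_231),
    ("12", 27_531_856, 21_029_590, 2_134_701),
]


@dataclass
class MappingSummary:
    table: pd.DataFrame  # chromosome, genome_bp, covered_bp, reads, coverage_pct
    total_genome_bp: int
    total_covered_bp: int
    total_reads: int
    average_coverage_pct: float
    min_coverage: tuple[str, float]
    max_coverage: tuple[str, float]


def coverage_report(
    rows: list[tuple[str, int, int, int]] | pd.DataFrame,
) -> MappingSummary:
    """Per-chromosome coverage percentages and their unweighted average.

    ``rows`` holds (chromosome, genome length bp, uniquely covered bases,
    uniquely mapped reads).  Each percentage is covered/length x 100 to 1
    decimal; the average is the unweighted mean across chromosomes, also
    to 1 decimal.  Covered bases exceeding the length is a hard error.
    """
    if isinstance(rows, pd.DataFrame):
        rows = [tuple(r) for r in rows.itertuples(index=False)]
    recs = []
    for chrom, length, covered, reads in rows:
        if covered > length:
            raise ValueError(f"chromosome {chrom}: covered bases exceed length")
        if length <= 0:
            raise ValueError(f"chromosome {chrom}: non-positive length")
        recs.append(
            {
                "chromosome": chrom,
                "genome_bp": length,
                "covered_bp": covered,
                "reads": reads,
                "coverage_pct": round_half_up(covered / length * 100, 1),
            }
        )
    table = pd.DataFrame(recs)
    pcts = [r["coverage_pct"] for r in recs]
    avg = round_half_up(sum(covered / length * 100 for _, length, covered, _ in rows) / len(rows), 1)
    i_min = min(range(len(pcts)), key=pcts.__getitem__)
    i_max = max(range(len(pcts)), key=pcts.__getitem__)
    return MappingSummary(
        table=table,
        total_genome_bp=sum(r["genome_bp"] for r in recs),
        total_covered_bp=sum(r["covered_bp"] for r in recs),
        total_reads=sum(r["reads"] for r in recs),
        average_coverage_pct=avg,
        min_coverage=(recs[i_min]["chromosome"], pcts[i_min]),
        max_coverage=(recs[i_max]["chromosome"], pcts[i_max]),
    )


def mapping_percentages(
    total_reads: float, mapped_reads: float, uniquely_mapped_reads: float
) -> tuple[float, float | None]:
    """(mapped % of total, uniquely-mapped % of *mapped*), each to 1 decimal.

    The unique percentage uses mapped reads as its denominator; it is
    ``None`` (undefined) when no reads mapped.
    """
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    if not (0 <= uniquely_mapped_reads <= mapped_reads <= total_reads):
        raise ValueError("require 0 <= unique <= mapped <= total")
    mapped_pct = round_half_up(mapped_reads / total_reads * 100, 1)
    unique_pct = (
        None if mapped_reads == 0
        else round_half_up(uniquely_mapped_reads / mapped_reads * 100, 1)
    )
    return (mapped_pct, unique_pct)


def variant_rate(total_genome_bases: int, total_passed_variants: int) -> int | str:
    """Bases per variant, truncated to an integer ("one variant every N
    bases"); undefined ("—") with zero variants."""
    if total_passed_variants == 0:
        return UNDEFINED
    if total_passed_variants < 0 or total_genome_bases < 0:
        raise ValueError("counts must be non-negative")
    return int(total_genome_bases // total_passed_variants)
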