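"""Box-plot outlier detection on per-gene non-synonymous SNP density.

Each gene's density is its non-synonymous SNP count divided by the genic
span length in kb (first to last exon, introns and UTRs included).  The
five-number summary (min, Q1, median, Q3, max) uses linear interpolation
between order statistics — the common box-and-whisker convention — and a
gene is an outlier when its density strictly exceeds the upper Tukey
fence Q3 + 1.5 * IQR.  Only the upper fence is applied: the distribution
of interest is right-skewed.  Genes with zero non-synonymous SNPs are
excluded from the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import VariantAnnotation
from .io_formats import GeneModel

TUKEY_K = 1.5


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def outlier_threshold(self) -> float:
        return self.q3 + TUKEY_K * self.iqr


def gene_ns_density(gene: GeneModel, annotations: list[VariantAnnotation]) -> float:
    """Non-synonymous SNPs per kb of genic region for one gene."""
    kb = gene.genic_length_kb
    if kb <= 0:
        raise ValueError(f"{gene.gene_id}: zero-length genic span")
    count = sum(
        a.gene_id == gene.gene_id and a.coding_effect == "non-synonymous"
        for a in annotations
    )
    return count / kb


def five_number_summary(densities) -> FiveNumberSummary:
    """Min, Q1, median, Q3, max with linear-interpolation quartiles."""
    values = np.asarray(list(densities), dtype=float)
    if values.size == 0:
        raise ValueError("five_number_summary requires at least one value")
    q0, q1, q2, q3, q4 = np.quantile(values, [0, 0.25, 0.5, 0.75, 1], method="linear")
    return FiveNumberSummary(float(q0), float(q1), float(q2), float(q3), float(q4))


def flag_outliers(
    gene_densities: dict[str, float], summary: FiveNumberSummary | None = None
) -> list[tuple[str, float, bool]]:
    """Flag genes whose density strictly exceeds Q3 + 1.5*IQR."""
    if summary is None:
        summary = five_number_summary(gene_densities.values())
    fence = summary.outlier_threshold
    return [(g, d, d > fence) for g, d in gene_densities.items()]


def gene_density_table(
    genes: list[GeneModel], annotations: list[VariantAnnotation]
) -> pd.DataFrame:
    """Per-gene density table over genes with >= 1 non-synonymous SNP.

    Columns: gene, nonsyn_count, genic_kb, density, outlier.
    """
    nonsyn = {}
    for a in annotations:
        if a.coding_effect == "non-synonymous":
            nonsyn[a.gene_id] = nonsyn.get(a.gene_id, 0) + 1
    carriers = [g for g in genes if nonsyn.get(g.gene_id, 0) > 0]
    if not carriers:
        return pd.DataFrame(
            columns=["gene", "nonsyn_count", "genic_kb", "density", "outlier"]
        )
    densities = {g.gene_id: nonsyn[g.gene_id] / g.genic_length_kb for g in carriers}
    summary = five_number_summary(densities.values())
    flags = dict(
        (g, flag) for g, _, flag in flag_outliers(densities, summary)
    )
    table = pd.DataFrame(
        {
            "gene": [g.gene_id for g in carriers],
            "nonsyn_count": [nonsyn[g.gene_id] for g in carriers],
            "genic_kb": [g.genic_length_kb for g in carriers],
            "density": [densities[g.gene_id] for g in carriers],
            "outlier": [flags[g.gene_id] for g in carriers],
        }
    )
    table.attrs["five_number_summary"] = summary
    return table
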