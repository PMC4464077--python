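"""Per-gene Ka/Ks from annotated variants and selection classification.

Ka is the count of non-synonymous coding SNPs in a gene and Ks the count
of synonymous ones; the ratio is the raw count ratio (not a per-site
Nei–Gojobori rate).  A gene is under neutral selection when Ka/Ks equals
1 exactly, negative when below 1, positive when above 1, and the ratio is
undefined (rendered "—") when Ks is 0.  Stop-gain/stop-loss and
start-gain/start-loss SNPs count in neither Ka nor Ks; they are tallied
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .annotation import VariantAnnotation

UNDEFINED = "—"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 0.85 -> 0.9), for display parity."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class GeneSelectionSummary:
    gene_id: str
    non_coding_snps: int
    ka: int
    ks: int
    non_coding_indels: int
    coding_indels: int
    start_stop_snps: int = 0

    @property
    def ka_ks(self) -> float | None:
        """Raw count ratio Ka/Ks, undefined when Ks is 0."""
        return None if self.ks == 0 else self.ka / self.ks

    @property
    def ka_ks_display(self) -> str:
        r = self.ka_ks
        return UNDEFINED if r is None else f"{round_half_up(r, 1):.1f}"

    @property
    def selection_class(self) -> str:
        r = self.ka_ks
        if r is None:
            return "undefined"
        if r == 1:
            return "neutral"
        return "negative" if r < 1 else "positive"


_GENIC_NONCODING = {"exon-5UTR", "exon-3UTR", "intron", "splice-site"}


def gene_selection(
    gene_id: str, annotations: list[VariantAnnotation]
) -> GeneSelectionSummary:
    """Tally one gene's coding/non-coding SNPs and InDels into a summary."""
    anns = [a for a in annotations if a.gene_id == gene_id]
    ka = sum(a.coding_effect == "non-synonymous" for a in anns)
    ks = sum(a.coding_effect == "synonymous" for a in anns)
    startstop = sum(
        a.coding_effect in ("stop-gain", "stop-loss", "start-gain", "start-loss")
        for a in anns
    )
    non_coding_snps = sum(
        a.record.is_snp and a.region_class in _GENIC_NONCODING and
        a.coding_effect in ("none", "start-gain")
        for a in anns
    )
    non_coding_indels = sum(
        a.record.is_indel and a.region_class in _GENIC_NONCODING for a in anns
    )
    coding_indels = sum(
        a.record.is_indel and a.region_class == "exon-CDS" for a in anns
    )
    return GeneSelectionSummary(
        gene_id=gene_id,
        non_coding_snps=non_coding_snps,
        ka=ka,
        ks=ks,
        non_coding_indels=non_coding_indels,
        coding_indels=coding_indels,
        start_stop_snps=startstop,
    )


def panel_report(
    gene_ids: list[str], annotations: list[VariantAnnotation]
) -> pd.DataFrame:
    """One row per panel gene plus a totals row.

    The aggregate Ka/Ks in the totals row is the ratio of summed counts,
    sum(Ka)/sum(Ks), to 1 decimal; per-class gene tallies are attached as
    DataFrame ``attrs['selection_tally']``.
    """
    summaries = [gene_selection(g, annotations) for g in gene_ids]
    rows = [
        {
            "gene": s.gene_id,
            "non_coding_snps": s.non_coding_snps,
            "ka": s.ka,
            "ks": s.ks,
            "ka_ks": s.ka_ks_display,
            "selection": s.selection_class,
            "non_coding_indels": s.non_coding_indels,
            "coding_indels": s.coding_indels,
        }
        for s in summaries
    ]
    if summaries:
        tot_ka = sum(s.ka for s in summaries)
        tot_ks = sum(s.ks for s in summaries)
        rows.append(
            {
                "gene": "Total/average",
                "non_coding_snps": sum(s.non_coding_snps for s in summaries),
                "ka": tot_ka,
                "ks": tot_ks,
                "ka_ks": UNDEFINED if tot_ks == 0 else f"{round_half_up(tot_ka / tot_ks, 1):.1f}",
                "selection": ".",
                "non_coding_indels": sum(s.non_coding_indels for s in summaries),
                "coding_indels": sum(s.coding_indels for s in summaries),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "non_coding_snps", "ka", "ks", "ka_ks", "selection",
            "non_coding_indels", "coding_indels",
        ],
    )
    tally = {"neutral": 0, "negative": 0, "positive": 0, "undefined": 0}
    for s in summaries:
        tally[s.selection_class] += 1
    table.attrs["selection_tally"] = tally
    return table
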