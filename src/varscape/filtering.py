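"""Five-criterion quality filter for called variants.

The filter keeps a variant only if (1) read depth is between 5 and 75,
(2) base quality >= 30, (3) mapping quality >= 60, (4) variant quality
>= 90, and (5) the nearest surviving variant on the same chromosome is at
least 5 bp away.  All bounds are inclusive on their stated side.  The
adjacency criterion runs after the four site criteria, so a low-quality
neighbour cannot kill a good variant, and it removes *both* members of a
close pair — the conservative reading when the aim is minimising false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import VariantRecord

CRITERIA = ("depth", "base-quality", "mapping-quality", "variant-quality", "adjacency")


@dataclass(frozen=True)
class FilterConfig:
    depth_min: int = 5
    depth_max: int = 75
    base_quality_min: float = 30.0
    mapping_quality_min: float = 60.0
    variant_quality_min: float = 90.0
    adjacency_min_distance: int = 5

    def __post_init__(self) -> None:
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")
        if min(self.depth_min, self.base_quality_min, self.mapping_quality_min,
               self.variant_quality_min, self.adjacency_min_distance) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterOutcome:
    record: VariantRecord
    failed_criteria: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


def apply_site_filters(
    records: list[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[FilterOutcome]:
    """Evaluate criteria (1)-(4) independently on each record.

    Thresholds are inclusive: depth exactly 5 or 75 passes, a quality
    exactly at its minimum passes.  Records must be sorted by
    (chromosome, position).
    """
    outcomes = []
    for r in records:
        failed = set()
        if not (config.depth_min <= r.depth <= config.depth_max):
            failed.add("depth")
        if r.base_quality < config.base_quality_min:
            failed.add("base-quality")
        if r.mapping_quality < config.mapping_quality_min:
            failed.add("mapping-quality")
        if r.variant_quality < config.variant_quality_min:
            failed.add("variant-quality")
        outcomes.append(FilterOutcome(r, failed))
    return outcomes


def apply_adjacency_filter(
    outcomes: list[FilterOutcome], config: FilterConfig = FilterConfig()
) -> list[FilterOutcome]:
    """Criterion (5): distance of adjacent variant >= 5.

    Among records that survived the site filters, every pair on the same
    chromosome whose POS values differ by less than the minimum distance
    gains the failure reason ``adjacency`` on *both* members.  Distance is
    measured between POS values regardless of allele length.
    """
    survivors = [o for o in outcomes if o.passed]
    survivors.sort(key=lambda o: o.record.sort_key)
    for a, b in zip(survivors, survivors[1:]):
        if (
            a.record.chromosome == b.record.chromosome
            and b.record.position - a.record.position < config.adjacency_min_distance
        ):
            a.failed_criteria.add("adjacency")
            b.failed_criteria.add("adjacency")
    return outcomes


def filter_variants(
    records: list[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[FilterOutcome]:
    """Run site filters then the adjacency filter; one outcome per record."""
    return apply_adjacency_filter(apply_site_filters(records, config), config)


def passed_records(outcomes: list[FilterOutcome]) -> list[VariantRecord]:
    return [o.record for o in outcomes if o.passed]
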