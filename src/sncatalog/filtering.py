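"""Per-genotype quality filters and the segregating-site admission rule.

The filters are deliberately permissive, mirroring the catalog-building
strategy: a genotype is removed when coverage is below 5-fold, above an
individual-specific ceiling (105-fold for the Altai Neanderthal, 75-fold for
the other individuals by default), when genotype quality is below 20, or when
a heterozygous call shows strong allele imbalance (minor-allele read fraction
below 0.2).  All four boundaries are strict inequalities, so DP=5, DP=105
(Altai), GQ=20 and minor fraction 0.2 all pass.

A failed genotype is treated downstream as missing, never as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .model import ArchaicGenotype, SiteObservation

FILTER_REASONS = ("ok", "low_coverage", "high_coverage", "low_gq",
                  "allele_imbalance", "missing")


@dataclass(frozen=True)
class FilterThresholds:
    """Quality thresholds, overridable per archaic individual for coverage."""

    dp_min: int = 5
    dp_max: Mapping[str, int] = field(
        default_factory=lambda: {"AltaiNeanderthal": 105})
    dp_max_default: int = 75
    gq_min: int = 20
    min_minor_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.min_minor_fraction <= 0.5:
            raise ValueError("min_minor_fraction must be in [0, 0.5]")
        for ind, cap in self.dp_max.items():
            if self.dp_min > cap:
                raise ValueError(f"dp_min {self.dp_min} exceeds dp_max for {ind}")
        if self.dp_min > self.dp_max_default:
            raise ValueError("dp_min exceeds default dp_max")

    def dp_max_for(self, individual_id: str) -> int:
        return self.dp_max.get(individual_id, self.dp_max_default)


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in FILTER_REASONS:
            raise ValueError(f"unknown filter reason {self.reason!r}")
        if self.passed != (self.reason == "ok"):
            raise ValueError("passed must hold exactly when reason is 'ok'")


def filter_genotype(g: ArchaicGenotype, t: FilterThresholds) -> FilterVerdict:
    """Apply the coverage / quality / allele-imbalance filters to one call.

    The imbalance rule only applies to heterozygous genotypes that carry
    allelic depths; heterozygotes without AD are passed on DP/GQ alone.
    """
    if g.is_missing:
        return FilterVerdict(False, "missing")
    if g.depth < t.dp_min:
        return FilterVerdict(False, "low_coverage")
    if g.depth > t.dp_max_for(g.individual_id):
        return FilterVerdict(False, "high_coverage")
    if g.genotype_quality < t.gq_min:
        return FilterVerdict(False, "low_gq")
    if g.is_heterozygous and g.allelic_depths is not None:
        total = sum(g.allelic_depths)
        if total > 0 and min(g.allelic_depths) / total < t.min_minor_fraction:
            return FilterVerdict(False, "allele_imbalance")
    return FilterVerdict(True, "ok")


def filter_site(s: SiteObservation, t: FilterThresholds) -> dict[str, FilterVerdict]:
    """Verdicts for every archaic genotype attached to a site."""
    return {ind: filter_genotype(g, t) for ind, g in s.archaic_genotypes.items()}


def admit_site(s: SiteObservation, verdicts: Mapping[str, FilterVerdict]) -> bool:
    """Segregating-site admission rule.

    A site enters the catalog when both alleles were observed — the reference
    allele is observed by definition (it is the human reference), and the
    alternative allele must appear either in the human cohort counts or in a
    passing archaic genotype — and at least one archaic genotype passed
    filtering (at least one covered archaic chromosome).
    """
    passing = [ind for ind, v in verdicts.items() if v.passed]
    if not passing:
        return False
    if s.alt_count > 0:
        return True
    for ind in passing:
        g = s.archaic_genotypes[ind]
        if s.alt_allele in g.alleles:
            return True
    return False
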