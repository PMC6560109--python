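"""Shared data model for the SNC catalog pipeline.

The unit of analysis is a biallelic single-nucleotide site with (i) diploid
genotypes for a small roster of archaic hominin individuals, (ii) present-day
human variation summarized as allele *counts* over a large cohort of
chromosomes, and (iii) an ancestral state inferred from a multiple-genome
alignment, with the macaque reference base as fallback.

All internal coordinates are 1-based inclusive (the VCF/GFF3 convention);
BED input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGT")

#: default archaic roster, matching the three published high-coverage genomes
DEFAULT_ROSTER = ("Denisovan", "AltaiNeanderthal", "VindijaNeanderthal")

#: individuals in the default roster that are Neanderthals
NEANDERTHALS = frozenset({"AltaiNeanderthal", "VindijaNeanderthal"})

#: chromosomes analyzed by default: 22 autosomes plus X (the archaic
#: individuals are female, so there is no Y data)
DEFAULT_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X"])


def autosome_or_x(chrom: str) -> bool:
    """True for the 22 autosomes and X, accepting an optional ``chr`` prefix."""
    return chrom.removeprefix("chr") in DEFAULT_CHROMOSOMES


@dataclass(frozen=True)
class ArchaicGenotype:
    """One diploid genotype call for one archaic individual.

    A genotype with either allele missing is treated as missing as a whole;
    depth and genotype quality are retained so filters can still report a
    reason.
    """

    individual_id: str
    allele1: Optional[str]
    allele2: Optional[str]
    depth: int = 0
    genotype_quality: int = 0
    allelic_depths: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.genotype_quality < 0:
            raise ValueError("depth and genotype quality must be non-negative")

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None or self.allele2 is None

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.allele1 != self.allele2

    @property
    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise ValueError("missing genotype has no alleles")
        return (self.allele1, self.allele2)  # type: ignore[return-value]


@dataclass(frozen=True)
class SiteObservation:
    """One biallelic genomic position with everything the classifier needs.

    Human variation is carried as reference/alternative allele counts; the
    derived-allele count and frequency only become meaningful after
    polarization against the ancestral state (see
    :mod:`sncatalog.classification`).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    ancestral: str = "unknown"  # one of {"ref", "alt", "unknown"}
    ancestral_source: str = "none"  # one of {"alignment", "macaque", "none"}
    macaque_allele: Optional[str] = None
    archaic_genotypes: dict[str, ArchaicGenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for b in (self.ref_allele, self.alt_allele):
            if b not in VALID_BASES:
                raise ValueError(f"not a single-base allele: {b!r}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.ref_count + self.alt_count <= 0:
            raise ValueError("total allele count must be positive")
        if self.ancestral not in ("ref", "alt", "unknown"):
            raise ValueError(f"bad ancestral state {self.ancestral!r}")
        if self.ancestral == "unknown" and self.ancestral_source != "none":
            raise ValueError("unknown ancestral state implies source 'none'")
        if self.ancestral != "unknown" and self.ancestral_source == "none":
            raise ValueError("known ancestral state needs a source")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def human_total_count(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def ancestral_allele(self) -> Optional[str]:
        if self.ancestral == "ref":
            return self.ref_allele
        if self.ancestral == "alt":
            return self.alt_allele
        return None

    @property
    def derived_allele(self) -> Optional[str]:
        if self.ancestral == "ref":
            return self.alt_allele
        if self.ancestral == "alt":
            return self.ref_allele
        return None

    @property
    def human_derived_count(self) -> Optional[int]:
        """Count of derived alleles in the human cohort; None if unpolarized."""
        if self.ancestral == "ref":
            return self.alt_count
        if self.ancestral == "alt":
            return self.ref_count
        return None


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript, 1-based inclusive intervals."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for s, e in self.exons + self.cds:
            if s > e:
                raise ValueError("interval start > end")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneRecord:
    """One gene with its genomic span and transcript models."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    is_transcription_factor: bool = False
    memberships: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        """Genomic span length (end - start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegulatoryFeature:
    """A non-genic annotation interval (1-based inclusive internally)."""

    chrom: str
    start: int
    end: int
    feature_class: str  # tfbs, mirna, regulatory_element, sweep_region, custom
    name: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("feature start > end")


@dataclass(frozen=True)
class TraitAssociation:
    """One (trait, gene) association, e.g. a GWAS catalog row."""

    trait_name: str
    gene_id: str
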