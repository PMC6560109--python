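"""Seeded synthetic input bundles with planted ground truth.

The generator emits every file the pipeline consumes — an archaic VCF, a
human allele-count table, an ancestral-allele track, a genome FASTA, GFF3
gene models, regulatory/sweep BED tracks and a trait table — together with
a truth table recording, for every emitted site, the intended category,
consequence class and filter fate, and for every gene the intended
enrichment flags.

Design: each planted site is constructed from a category *template* (a
genotype/frequency pattern that satisfies exactly that category's defining
predicate and no stronger one), so the classifier's output can be diffed
against the truth table site by site.  Distractor sites violate exactly one
quality filter.  Coding sites are placed at codon positions engineered to
yield the intended missense/synonymous class, independently of the
annotation module.  The generator targets predicate coverage, not
population-genetic realism: there is no coalescent, recombination or
demography.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as sio
from .model import (DEFAULT_ROSTER, GeneRecord, RegulatoryFeature,
                    TraitAssociation, TranscriptModel)

logger = logging.getLogger("sncatalog")

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

HUMAN_CATEGORIES = ("fixed_human", "hf_human", "extended_a", "extended_b",
                    "extended_c", "extended_d")
ARCHAIC_CATEGORIES = ("fixed_archaic", "hf_archaic", "extended_archaic")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic bundle.

    The cohort size mirrors the 1000 Genomes phase-3 scale (5,008
    chromosomes) so that "fixed" and ">99.999% ancestral" are expressible as
    exact counts.  Archaic depths are drawn from a negative binomial with
    mean ~40 reads, truncated to the planted filter fate.
    """

    rng_seed: int = 0
    cohort_chromosomes: int = 5008
    roster: tuple[str, ...] = DEFAULT_ROSTER
    chromosome_names: tuple[str, ...] = ("1", "2", "3", "X")
    n_ordinary_genes: int = 100
    gene_length_log_mean: float = 9.3
    gene_length_log_sd: float = 0.45
    gene_length_min: int = 2500
    gene_length_max: int = 60000
    category_counts: dict = field(default_factory=lambda: {
        "fixed_human": 60, "hf_human": 80, "extended_a": 35, "extended_b": 35,
        "extended_c": 35, "extended_d": 35, "fixed_archaic": 50,
        "hf_archaic": 80, "extended_archaic": 35})
    background_sites: int = 150
    distractor_counts: dict = field(default_factory=lambda: {
        "low_coverage": 12, "high_coverage": 12, "low_gq": 12,
        "allele_imbalance": 12})
    epo_mismatch_sites: int = 5
    gene_hf_rate: float = 0.0009  # per bp per lineage
    gene_background_rate: float = 0.0005
    min_sites_per_gene: int = 27
    missense_fraction: float = 0.35
    synonymous_fraction: float = 0.20
    n_density_enriched: int = 5
    density_multiplier: float = 10.0
    n_ratio_enriched: int = 6  # per lineage
    ratio_onesided_count: int = 27
    plant_boundary_genes: bool = True
    n_traits: int = 25
    genes_per_trait: int = 12
    trait_excess_multiplier: float = 5.0
    planted_trait_name: str = "planted_trait"
    n_sweep_regions: int = 3
    n_tfbs: int = 40
    n_mirna: int = 12
    n_regulatory: int = 40
    upstream_window: int = 5000
    depth_nbinom_n: float = 20.0
    depth_nbinom_p: float = 1 / 3  # mean 40
    het_fraction: float = 0.2  # of fixed-archaic sites carrying one het call

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedBundle:
    """Paths to every emitted file plus the in-memory truth tables."""

    directory: Path
    vcf: Path
    frequency_table: Path
    ancestral_track: Path
    genome_fasta: Path
    gene_models: Path
    tfbs_bed: Path
    mirna_bed: Path
    regulatory_bed: Path
    sweeps_bed: Path
    trait_table: Path
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_traits: pd.DataFrame
    manifest: Path


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

class _Genome:
    def __init__(self) -> None:
        self.seqs: dict[str, bytearray] = {}

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.seqs[chrom][pos - 1])

    def set_seq(self, chrom: str, start: int, seq: str) -> None:
        self.seqs[chrom][start - 1:start - 1 + len(seq)] = seq.encode()


@dataclass
class _Gene:
    record: GeneRecord
    cds: list[tuple[int, int]]
    intron: tuple[int, int]
    utr5: tuple[int, int]
    utr3: tuple[int, int]
    role: str = "ordinary"  # ordinary/density/ratio_human/ratio_archaic/boundary_*


_SAFE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in STOP_CODONS and a + b + c != "ATG"]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(len(_SAFE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SAFE_CODONS[i] for i in idx) + "TAA"


def _coding_layout(gene: _Gene) -> tuple[str, list[int]]:
    """(placeholder CDS orientation helper) genomic positions of the CDS in
    coding order, for strand-aware codon arithmetic."""
    pos_list = [p for s, e in sorted(gene.cds) for p in range(s, e + 1)]
    if gene.record.strand == "-":
        pos_list = pos_list[::-1]
    return gene.record.strand, pos_list


def _revcomp_base(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


class _SitePlanner:
    """Tracks used positions and places sites by target consequence class."""

    def __init__(self, rng: np.random.Generator, genome: _Genome,
                 genes: list[_Gene], window: int) -> None:
        self.rng = rng
        self.genome = genome
        self.genes = genes
        self.window = window
        self.used: dict[str, set[int]] = {c: set() for c in genome.seqs}
        self.safe_zones: dict[str, list[tuple[int, int]]] = {}

    def reserve(self, chrom: str, pos: int) -> bool:
        if pos in self.used[chrom]:
            return False
        self.used[chrom].add(pos)
        return True

    def compute_safe_zones(self) -> None:
        pad = self.window + 300
        for chrom, seq in self.genome.seqs.items():
            spans = sorted((g.record.start - pad, g.record.end + pad)
                           for g in self.genes if g.record.chrom == chrom)
            zones, cursor = [], 500
            for s, e in spans:
                if s - cursor > 400:
                    zones.append((cursor, s - 1))
                cursor = max(cursor, e + 1)
            if len(seq) - 500 - cursor > 400:
                zones.append((cursor, len(seq) - 500))
            self.safe_zones[chrom] = zones

    def place_intergenic(self, chrom: Optional[str] = None) -> tuple[str, int]:
        chroms = [chrom] if chrom else [c for c, z in self.safe_zones.items() if z]
        for _ in range(1000):
            c = chroms[self.rng.integers(len(chroms))]
            zones = self.safe_zones[c]
            s, e = zones[self.rng.integers(len(zones))]
            pos = int(self.rng.integers(s, e + 1))
            if self.reserve(c, pos):
                return c, pos
        raise RuntimeError("could not place intergenic site")

    def place_in_interval(self, chrom: str, start: int, end: int) -> Optional[int]:
        if end < start:
            return None
        for _ in range(200):
            pos = int(self.rng.integers(start, end + 1))
            if self.reserve(chrom, pos):
                return pos
        return None

    def place_coding(self, gene: _Gene, target: str) -> tuple[int, str, str]:
        """Position + (ref, alt) bases achieving `target` (missense or
        synonymous) in the gene's transcript, engineered by codon arithmetic."""
        strand, pos_list = _coding_layout(gene)
        chrom = gene.record.chrom
        cds_seq = "".join(self.genome.base(chrom, p) for p in
                          sorted(p for p in pos_list))
        if strand == "-":
            cds_seq = str(Seq(cds_seq).reverse_complement())
        n_codons = len(cds_seq) // 3
        for _ in range(500):
            codon_i = int(self.rng.integers(1, n_codons - 1))  # skip start/stop
            within = int(self.rng.integers(3))
            coding_idx = codon_i * 3 + within
            gpos = pos_list[coding_idx]
            if gpos in self.used[chrom]:
                continue
            codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
            ref_aa = str(Seq(codon).translate())
            order = self.rng.permutation(4)
            for bi in order:
                alt_cb = BASES[bi]
                if alt_cb == codon[within]:
                    continue
                alt_codon = codon[:within] + alt_cb + codon[within + 1:]
                alt_aa = str(Seq(alt_codon).translate())
                if alt_aa == "*" or ref_aa == "*":
                    continue
                cls = "synonymous" if alt_aa == ref_aa else "missense"
                if cls != target:
                    continue
                self.used[chrom].add(gpos)
                ref_b = self.genome.base(chrom, gpos)
                alt_b = alt_cb if strand == "+" else _revcomp_base(alt_cb)
                return gpos, ref_b, alt_b
        raise RuntimeError(f"could not place {target} site in {gene.record.gene_id}")

    def place_noncoding(self, gene: _Gene, target: str) -> Optional[int]:
        c = gene.record.chrom
        if target == "intronic":
            s, e = gene.intron
            return self.place_in_interval(c, s + 3, e - 3)
        if target == "splice_site":
            s, e = gene.intron
            options = [s, s + 1, e - 1, e]
            self.rng.shuffle(options)
            for pos in options:
                if self.reserve(c, int(pos)):
                    return int(pos)
            return None
        if target == "five_prime_utr":
            s, e = gene.utr5
            return self.place_in_interval(c, s, e)
        if target == "three_prime_utr":
            s, e = gene.utr3
            return self.place_in_interval(c, s, e)
        if target in ("upstream", "downstream"):
            # strand-aware: upstream is 5' of the transcript start
            left = (target == "upstream") == (gene.record.strand == "+")
            if left:
                return self.place_in_interval(
                    c, gene.record.start - self.window + 100,
                    gene.record.start - 10)
            return self.place_in_interval(
                c, gene.record.end + 10, gene.record.end + self.window - 100)
        raise ValueError(target)


# ---------------------------------------------------------------------------
# category templates
# ---------------------------------------------------------------------------

def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig,
                individual: str) -> int:
    cap = 105 if individual == "AltaiNeanderthal" else 75
    d = int(rng.negative_binomial(cfg.depth_nbinom_n, cfg.depth_nbinom_p))
    return int(np.clip(d, 5, cap - 5))


def _genotype(rng, cfg, individual, state, anc, der, third=None):
    """(allele1, allele2, DP, GQ, AD) tuple for a passing genotype in the
    given carrier state."""
    dp = _draw_depth(rng, cfg, individual)
    gq = int(rng.integers(20, 99))
    if state == "missing":
        return (None, None, dp, gq, None)
    if state == "ancestral_hom":
        return (anc, anc, dp, gq, (dp, 0))
    if state == "derived_hom":
        return (der, der, dp, gq, (dp, 0))
    if state == "other_allele":
        return (third, third, dp, gq, (dp, 0))
    # heterozygous, balanced allelic depths (minor fraction >= 0.3)
    minor = max(2, int(dp * rng.uniform(0.3, 0.5)))
    return (anc, der, dp, gq, (dp - minor, minor))


def _failing_genotype(rng, cfg, individual, reason, a, b):
    cap = 105 if individual == "AltaiNeanderthal" else 75
    gq = int(rng.integers(20, 99))
    if reason == "low_coverage":
        return (a, a, int(rng.integers(0, 5)), gq, None)
    if reason == "high_coverage":
        return (a, a, int(rng.integers(cap + 1, cap + 40)), gq, None)
    if reason == "low_gq":
        return (a, a, _draw_depth(rng, cfg, individual), int(rng.integers(0, 20)), None)
    # allele imbalance: heterozygous with minor fraction < 0.2
    dp = int(rng.integers(20, 60))
    minor = max(1, int(dp * rng.uniform(0.02, 0.15)))
    return (a, b, dp, gq, (dp - minor, minor))


def _human_counts(rng, cfg, category: str) -> tuple[int, int]:
    """(derived_count, total).  Frequencies satisfy the category's strict
    inequalities with margin for the count representation."""
    n = cfg.cohort_chromosomes
    if category == "fixed_human":
        return n, n
    if category in ("hf_human", "extended_a", "extended_b", "extended_c",
                    "extended_d"):
        return int(rng.integers(int(0.905 * n), n - 1)), n
    if category == "fixed_archaic":
        return 0, n
    if category in ("hf_archaic", "extended_archaic"):
        return int(rng.integers(1, int(0.0095 * n))), n
    # background / distractors: mid-frequency, unclassifiable
    return int(rng.integers(int(0.05 * n), int(0.85 * n))), n


def _states_for(rng, cfg, category: str) -> dict[str, str]:
    """Carrier-state pattern satisfying the category predicate and no
    stronger one (evaluated under strict 'carries ancestral' semantics)."""
    den, altai, vindija = "Denisovan", "AltaiNeanderthal", "VindijaNeanderthal"
    neand = [altai, vindija]
    rng.shuffle(neand)
    n1, n2 = neand
    if category == "fixed_human":
        pattern = int(rng.integers(3))
        if pattern == 0:
            return {den: "ancestral_hom", n1: "ancestral_hom", n2: "ancestral_hom"}
        third = "derived_hom" if pattern == 1 else "heterozygous"
        return {den: "ancestral_hom", n1: "ancestral_hom", n2: third}
    if category == "hf_human":
        other = "derived_hom" if rng.integers(2) else "heterozygous"
        return {den: "ancestral_hom", n1: "ancestral_hom", n2: other}
    if category == "extended_a":
        pattern = int(rng.integers(3))
        if pattern == 0:  # Denisovan missing, Neanderthals ancestral
            return {den: "missing", n1: "ancestral_hom", n2: "ancestral_hom"}
        if pattern == 1:
            return {den: "missing", n1: "missing", n2: "ancestral_hom"}
        return {den: "ancestral_hom", n1: "missing", n2: "missing"}
    if category == "extended_b":
        if rng.integers(2):
            return {den: "other_allele", n1: "ancestral_hom", n2: "ancestral_hom"}
        return {den: "ancestral_hom", n1: "other_allele", n2: "other_allele"}
    if category == "extended_c":
        pattern = int(rng.integers(3))
        if pattern == 0:
            return {den: "ancestral_hom", n1: "derived_hom", n2: "derived_hom"}
        if pattern == 1:
            return {den: "ancestral_hom", n1: "derived_hom", n2: "missing"}
        return {den: "ancestral_hom", n1: "heterozygous", n2: "derived_hom"}
    if category == "extended_d":
        return {den: "ancestral_hom", n1: "ancestral_hom", n2: "ancestral_hom"}
    if category == "fixed_archaic":
        states = {den: "derived_hom", n1: "derived_hom", n2: "derived_hom"}
        if rng.random() < cfg.het_fraction:
            states[n2] = "heterozygous"  # still carries the derived allele
        return states
    if category == "hf_archaic":
        third = "ancestral_hom" if rng.integers(2) else "missing"
        return {den: "derived_hom", n1: "derived_hom", n2: third}
    if category == "extended_archaic":
        third = "ancestral_hom" if rng.integers(2) else "missing"
        return {den: "derived_hom", n1: "derived_hom", n2: third}
    # background: anything that cannot be classified at mid frequency;
    # at least one reliable genotype so the site stays admissible
    states = {}
    for ind in (den, n1, n2):
        states[ind] = ("ancestral_hom", "derived_hom", "heterozygous",
                       "missing")[int(rng.integers(4))]
    if all(st == "missing" for st in states.values()):
        states[den] = "heterozygous"
    return states


_CATEGORY_LABEL = {
    "fixed_human": ("human", "fixed", None),
    "hf_human": ("human", "high_frequency", None),
    "extended_a": ("human", "extended", "a"),
    "extended_b": ("human", "extended", "b"),
    "extended_c": ("human", "extended", "c"),
    "extended_d": ("human", "extended", "d"),
    "fixed_archaic": ("archaic", "fixed", None),
    "hf_archaic": ("archaic", "high_frequency", None),
    "extended_archaic": ("archaic", "extended", "macaque_match"),
    "background": ("none", "none", None),
}


class _SiteEmitter:
    """Accumulates planted sites into the VCF/frequency/ancestral tables."""

    def __init__(self, rng, cfg: SimulationConfig) -> None:
        self.rng = rng
        self.cfg = cfg
        self.vcf_rows: list[sio.VcfRow] = []
        self.counts: dict[tuple, tuple[int, int]] = {}
        self.ancestral: dict[tuple, tuple] = {}
        self.truth_rows: list[dict] = []
        self.positions: set[tuple[str, int]] = set()

    def emit(self, chrom: str, pos: int, ref: str, alt: str, category: str,
             consequence: str, gene_id: Optional[str],
             filter_fate: str = "admitted") -> None:
        rng, cfg = self.rng, self.cfg
        if (chrom, pos) in self.positions:
            raise RuntimeError(f"duplicate planted position {chrom}:{pos}")
        self.positions.add((chrom, pos))
        derived_is_alt = bool(rng.random() < 0.7)
        anc, der = (ref, alt) if derived_is_alt else (alt, ref)
        third = next(b for b in BASES if b not in (ref, alt))

        d, n = _human_counts(rng, cfg, category)
        alt_count = d if derived_is_alt else n - d
        self.counts[(chrom, pos, ref, alt)] = (n - alt_count, alt_count)

        if filter_fate != "admitted":
            genotypes = {ind: _failing_genotype(rng, cfg, ind, filter_fate,
                                                anc, der)
                         for ind in cfg.roster}
            epo, mac = anc, anc
            label = ("none", "none", None)
        else:
            states = _states_for(rng, cfg, category)
            genotypes = {ind: _genotype(rng, cfg, ind, states[ind], anc, der,
                                        third)
                         for ind in cfg.roster}
            # half of the incomplete-genotype (extended a) sites realize the
            # missing call as a failing genotype rather than ./.
            if category == "extended_a":
                for ind, st in states.items():
                    if st == "missing" and rng.integers(2):
                        reason = ("low_coverage", "low_gq")[int(rng.integers(2))]
                        genotypes[ind] = _failing_genotype(
                            rng, cfg, ind, reason, anc, anc)
            if category in ("extended_d", "extended_archaic"):
                epo, mac = None, anc
            else:
                epo, mac = anc, (anc if rng.random() < 0.8 else None)
            label = _CATEGORY_LABEL[category]

        self.ancestral[(chrom, pos)] = (epo, mac)
        alts = [alt]
        if any(g[0] == third or g[1] == third for g in genotypes.values()):
            alts.append(third)
        self.vcf_rows.append(sio.VcfRow(chrom=chrom, pos=pos, ref=ref,
                                        alts=tuple(alts), genotypes=genotypes))
        self.truth_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "planted_category": category, "lineage": label[0],
            "category": label[1], "extended_condition": label[2] or "",
            "consequence_class": consequence, "filter_fate": filter_fate,
            "gene_id": gene_id or "",
            "derived_freq": d / n,
        })


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def simulate_bundle(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedBundle:
    """Generate a complete input bundle plus truth tables under ``out_dir``."""
    rng = np.random.default_rng(cfg.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = _layout_genes(rng, cfg)
    genome = _build_genome(rng, cfg, genes)
    planner = _SitePlanner(rng, genome, genes, cfg.upstream_window)
    planner.compute_safe_zones()
    emitter = _SiteEmitter(rng, cfg)

    features = _place_features(rng, cfg, planner)
    gene_truth, trait_truth, traits = _plant_everything(
        rng, cfg, genes, planner, emitter, features)

    # decoy scaffold rows: dropped by the autosome+X restriction
    for i in range(3):
        emitter.counts[("GL000220", 1000 + i, "A", "G")] = (100, 100)

    paths = _write_bundle(cfg, out, genome, genes, features, traits, emitter,
                          gene_truth, trait_truth)
    return paths


def _layout_genes(rng: np.random.Generator, cfg: SimulationConfig) -> list[_Gene]:
    roles = (["ordinary"] * cfg.n_ordinary_genes
             + ["density"] * cfg.n_density_enriched
             + ["ratio_human"] * cfg.n_ratio_enriched
             + ["ratio_archaic"] * cfg.n_ratio_enriched)
    if cfg.plant_boundary_genes:
        roles += ["boundary_short", "boundary_few_segregating",
                  "boundary_low_combined"]
    rng.shuffle(roles)

    cursors = {c: 30_000 for c in cfg.chromosome_names}
    genes: list[_Gene] = []
    for i, role in enumerate(roles):
        chrom = cfg.chromosome_names[i % len(cfg.chromosome_names)]
        if role == "boundary_short":
            length = 4999
        elif role == "boundary_few_segregating":
            length = 5200
        elif role == "boundary_low_combined":
            length = 20000
        else:
            length = int(np.clip(rng.lognormal(cfg.gene_length_log_mean,
                                               cfg.gene_length_log_sd),
                                 cfg.gene_length_min, cfg.gene_length_max))
            if role in ("density", "ratio_human", "ratio_archaic"):
                # planted-enrichment genes must clear the 5,000 bp
                # eligibility floor by construction
                length = max(length, 6000)
        start = cursors[chrom]
        end = start + length - 1
        cursors[chrom] = end + 14_000 + int(rng.integers(0, 4000))
        strand = "+" if rng.random() < 0.7 else "-"
        u5, u3, intron_len = (int(rng.integers(60, 200)),
                              int(rng.integers(80, 240)),
                              int(rng.integers(150, 400)))
        cds_total = (length - u5 - u3 - intron_len) // 3 * 3
        cds1 = max(60, cds_total // 2 // 3 * 3 + 1)  # mid-codon split allowed
        # genomic left-to-right: [utr_left][CDS1][intron][CDS2][utr_right]
        utr_left = (start, start + u5 - 1)
        cds1_iv = (start + u5, start + u5 + cds1 - 1)
        intron_iv = (cds1_iv[1] + 1, cds1_iv[1] + intron_len)
        cds2_iv = (intron_iv[1] + 1, intron_iv[1] + (cds_total - cds1))
        utr_right = (cds2_iv[1] + 1, end)
        gid = f"GENE{i:04d}"
        tx = TranscriptModel(
            transcript_id=f"{gid}.t1",
            exons=((utr_left[0], cds1_iv[1]), (cds2_iv[0], utr_right[1])),
            cds=(cds1_iv, cds2_iv))
        rec = GeneRecord(gene_id=gid, gene_name=gid, chrom=chrom, start=start,
                         end=end, strand=strand, transcripts=[tx])
        utr5, utr3 = ((utr_left, utr_right) if strand == "+"
                      else (utr_right, utr_left))
        genes.append(_Gene(record=rec, cds=[cds1_iv, cds2_iv],
                           intron=intron_iv, utr5=utr5, utr3=utr3, role=role))
    return genes


def _build_genome(rng: np.random.Generator, cfg: SimulationConfig,
                  genes: list[_Gene]) -> _Genome:
    genome = _Genome()
    ends = {c: 60_000 for c in cfg.chromosome_names}
    for g in genes:
        ends[g.record.chrom] = max(ends[g.record.chrom], g.record.end + 30_000)
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for chrom in cfg.chromosome_names:
        seq = base_codes[rng.integers(4, size=ends[chrom])]
        genome.seqs[chrom] = bytearray(seq.tobytes())
    for g in genes:
        cds_total = sum(e - s + 1 for s, e in g.cds)
        coding = _random_cds(rng, cds_total // 3)
        genomic = coding if g.record.strand == "+" else \
            str(Seq(coding).reverse_complement())
        offset = 0
        for s, e in sorted(g.cds):
            genome.set_seq(g.record.chrom, s, genomic[offset:offset + e - s + 1])
            offset += e - s + 1
    return genome


def _place_features(rng, cfg: SimulationConfig, planner: _SitePlanner
                    ) -> dict[str, list[RegulatoryFeature]]:
    """Disjoint regulatory intervals in intergenic safe zones."""
    feats: dict[str, list[RegulatoryFeature]] = {
        "tfbs": [], "mirna": [], "regulatory_element": []}
    specs = ([("tfbs", 15)] * cfg.n_tfbs + [("mirna", 80)] * cfg.n_mirna
             + [("regulatory_element", 400)] * cfg.n_regulatory)
    for i, (cls, size) in enumerate(specs):
        for _ in range(200):
            chrom, pos = planner.place_intergenic()
            start, end = pos, pos + size - 1
            clash = any(f.chrom == chrom and not (end < f.start - 5 or
                                                  start > f.end + 5)
                        for lst in feats.values() for f in lst)
            if not clash:
                feats[cls].append(RegulatoryFeature(
                    chrom=chrom, start=start, end=end, feature_class=cls,
                    name=f"{cls}{i}"))
                # reserve interior so feature sites are placed explicitly
                planner.used[chrom].update(range(start, end + 1))
                break
    return feats


def _plant_everything(rng, cfg: SimulationConfig, genes: list[_Gene],
                      planner: _SitePlanner, emitter: _SiteEmitter,
                      features) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    ordinary = [g for g in genes if g.role == "ordinary"]
    special = [g for g in genes if g.role != "ordinary"]

    # trait table: planted trait genes get a missense excess
    trait_pool = [g.record.gene_id for g in ordinary]
    planted_trait_genes = list(rng.choice(trait_pool, cfg.genes_per_trait,
                                          replace=False))
    other_pool = [g for g in trait_pool if g not in set(planted_trait_genes)]
    traits: list[TraitAssociation] = []
    for g in planted_trait_genes:
        traits.append(TraitAssociation(cfg.planted_trait_name, g))
    for t in range(cfg.n_traits - 1):
        for g in rng.choice(other_pool, cfg.genes_per_trait, replace=False):
            traits.append(TraitAssociation(f"trait_{t:03d}", str(g)))
    for g in rng.choice(other_pool, 9, replace=False):  # undersized trait
        traits.append(TraitAssociation("undersized_trait", str(g)))

    # per-gene planted HF sites
    planted_set = set(planted_trait_genes)
    gene_rows = []
    for g in genes:
        L = g.record.length_bp
        lam = cfg.gene_hf_rate * L
        if g.role == "density":
            n_h = int(rng.poisson(lam * cfg.density_multiplier))
            n_a = int(rng.poisson(lam))
        elif g.role == "ratio_human":
            n_h, n_a = cfg.ratio_onesided_count, 0
        elif g.role == "ratio_archaic":
            n_h, n_a = 0, cfg.ratio_onesided_count
        elif g.role == "boundary_short":
            n_h, n_a = 30, 25
        elif g.role == "boundary_few_segregating":
            n_h, n_a = 12, 12
        elif g.role == "boundary_low_combined":
            n_h, n_a = 19, 0
        else:
            n_h, n_a = int(rng.poisson(lam)), int(rng.poisson(lam))

        n_mis_h = int(round(cfg.missense_fraction * n_h))
        if g.record.gene_id in planted_set:
            n_mis_h = int(round(n_mis_h * cfg.trait_excess_multiplier))
            n_h = n_h - int(round(cfg.missense_fraction * n_h)) + n_mis_h
        n_syn_h = int(round(cfg.synonymous_fraction * n_h))
        n_mis_a = int(round(cfg.missense_fraction * n_a))
        n_syn_a = int(round(cfg.synonymous_fraction * n_a))

        n_bg = int(rng.poisson(cfg.gene_background_rate * L))
        if g.role == "boundary_few_segregating":
            n_bg = 0
        elif g.role == "boundary_short":
            n_bg = 0
        else:
            n_bg = max(n_bg, cfg.min_sites_per_gene - n_h - n_a)

        for lineage, n_all, n_mis, n_syn in (
                ("hf_human", n_h, n_mis_h, n_syn_h),
                ("hf_archaic", n_a, n_mis_a, n_syn_a)):
            for j in range(n_all):
                if j < n_mis:
                    target = "missense"
                elif j < n_mis + n_syn:
                    target = "synonymous"
                else:
                    target = "intronic"
                _plant_in_gene(planner, emitter, g, lineage, target)
        for _ in range(max(0, n_bg)):
            _plant_in_gene(planner, emitter, g, "background", "intronic")

        gene_rows.append({
            "gene_id": g.record.gene_id, "role": g.role,
            "planted_hf_human": n_h, "planted_hf_archaic": n_a,
            "density_enriched_human": g.role == "density",
            "ratio_enriched_human": g.role == "ratio_human",
            "ratio_enriched_archaic": g.role == "ratio_archaic",
        })

    # global category sites across placement types
    placements = [("missense", 0.14), ("synonymous", 0.14),
                  ("intronic", 0.12), ("splice_site", 0.05),
                  ("five_prime_utr", 0.05), ("three_prime_utr", 0.05),
                  ("upstream", 0.10), ("downstream", 0.10), ("tfbs", 0.08),
                  ("mirna", 0.04), ("regulatory_element", 0.08),
                  ("intergenic", 0.05)]
    names = [p for p, _ in placements]
    weights = np.array([w for _, w in placements])
    weights /= weights.sum()
    for category, count in cfg.category_counts.items():
        for _ in range(count):
            target = names[int(rng.choice(len(names), p=weights))]
            _plant_global(rng, planner, emitter, ordinary, features, category,
                          target)
    for _ in range(cfg.background_sites):
        chrom, pos = planner.place_intergenic()
        ref = planner.genome.base(chrom, pos)
        alt = _other_base(rng, ref)
        emitter.emit(chrom, pos, ref, alt, "background", "intergenic", None)
    for reason, count in cfg.distractor_counts.items():
        for _ in range(count):
            chrom, pos = planner.place_intergenic()
            ref = planner.genome.base(chrom, pos)
            alt = _other_base(rng, ref)
            emitter.emit(chrom, pos, ref, alt, "background", "intergenic",
                         None, filter_fate=reason)
    # EPO allele matching neither ref nor alt: polarization falls back to
    # unknown with a tally
    for _ in range(cfg.epo_mismatch_sites):
        chrom, pos = planner.place_intergenic()
        ref = planner.genome.base(chrom, pos)
        alt = _other_base(rng, ref)
        emitter.emit(chrom, pos, ref, alt, "background", "intergenic", None)
        third = next(b for b in BASES if b not in (ref, alt))
        emitter.ancestral[(chrom, pos)] = (third, None)

    gene_truth = pd.DataFrame(gene_rows)
    trait_truth = pd.DataFrame([
        {"trait": cfg.planted_trait_name, "enriched_lineage": "human",
         "excess_multiplier": cfg.trait_excess_multiplier}])
    return gene_truth, trait_truth, traits


def _other_base(rng, ref: str) -> str:
    others = [b for b in BASES if b != ref]
    return others[int(rng.integers(3))]


def _plant_in_gene(planner: _SitePlanner, emitter: _SiteEmitter, g: _Gene,
                   category: str, target: str) -> None:
    chrom = g.record.chrom
    if target in ("missense", "synonymous"):
        try:
            pos, ref, alt = planner.place_coding(g, target)
        except RuntimeError:
            pos = planner.place_noncoding(g, "intronic")
            if pos is None:
                return
            target = "intronic"
            ref = planner.genome.base(chrom, pos)
            alt = _other_base(planner.rng, ref)
    else:
        pos = planner.place_noncoding(g, target)
        if pos is None:
            return
        ref = planner.genome.base(chrom, pos)
        alt = _other_base(planner.rng, ref)
    emitter.emit(chrom, pos, ref, alt, category, target, g.record.gene_id)


def _plant_global(rng, planner: _SitePlanner, emitter: _SiteEmitter,
                  ordinary: list[_Gene], features, category: str,
                  target: str) -> None:
    if target in ("tfbs", "mirna", "regulatory_element"):
        pool = features[target]
        for _ in range(100):
            f = pool[int(rng.integers(len(pool)))]
            pos = int(rng.integers(f.start, f.end + 1))
            if (f.chrom, pos) not in emitter.positions:
                ref = planner.genome.base(f.chrom, pos)
                alt = _other_base(rng, ref)
                emitter.emit(f.chrom, pos, ref, alt, category, target, None)
                return
        return
    if target == "intergenic":
        chrom, pos = planner.place_intergenic()
        ref = planner.genome.base(chrom, pos)
        alt = _other_base(rng, ref)
        emitter.emit(chrom, pos, ref, alt, category, target, None)
        return
    g = ordinary[int(rng.integers(len(ordinary)))]
    _plant_in_gene(planner, emitter, g, category, target)


def _write_bundle(cfg, out: Path, genome: _Genome, genes: list[_Gene],
                  features, traits, emitter: _SiteEmitter,
                  gene_truth: pd.DataFrame, trait_truth: pd.DataFrame
                  ) -> SimulatedBundle:
    paths = {name: out / fname for name, fname in [
        ("vcf", "archaic.vcf"), ("frequency_table", "human_counts.tsv"),
        ("ancestral_track", "ancestral.tsv"), ("genome_fasta", "genome.fa"),
        ("gene_models", "genes.gff3"), ("tfbs_bed", "tfbs.bed"),
        ("mirna_bed", "mirna.bed"), ("regulatory_bed", "regulatory.bed"),
        ("sweeps_bed", "sweeps.bed"), ("trait_table", "traits.tsv"),
    ]}
    rows = sorted(emitter.vcf_rows, key=lambda r: (r.chrom, r.pos))
    contigs = [(c, len(s)) for c, s in genome.seqs.items()]
    sio.write_archaic_vcf(rows, paths["vcf"], cfg.roster, contigs)
    sio.write_frequency_table(emitter.counts, paths["frequency_table"])
    sio.write_ancestral_track(emitter.ancestral, paths["ancestral_track"])
    with open(paths["genome_fasta"], "w") as fh:
        for chrom, seq in genome.seqs.items():
            fh.write(f">{chrom}\n")
            s = seq.decode()
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
    sio.write_gene_models([g.record for g in genes], paths["gene_models"])
    sio.write_bed_features(features["tfbs"], paths["tfbs_bed"])
    sio.write_bed_features(features["mirna"], paths["mirna_bed"])
    sio.write_bed_features(features["regulatory_element"], paths["regulatory_bed"])
    sweeps = _sweep_regions(cfg, genes)
    sio.write_bed_features(sweeps, paths["sweeps_bed"])
    sio.write_trait_table(traits, paths["trait_table"])

    truth_columns = ["chrom", "pos", "ref", "alt", "planted_category",
                     "lineage", "category", "extended_condition",
                     "consequence_class", "filter_fate", "gene_id",
                     "derived_freq"]
    truth_sites = pd.DataFrame(emitter.truth_rows,
                               columns=truth_columns).sort_values(
        ["chrom", "pos"]).reset_index(drop=True)
    truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    trait_truth.to_csv(out / "truth_traits.tsv", sep="\t", index=False)

    manifest = out / "manifest.json"
    manifest.write_text(json.dumps(
        {"seed": cfg.rng_seed, "config_hash": cfg.config_hash(),
         "files": {k: p.name for k, p in paths.items()}},
        indent=2, sort_keys=True) + "\n")
    return SimulatedBundle(directory=out, truth_sites=truth_sites,
                           truth_genes=gene_truth, truth_traits=trait_truth,
                           manifest=manifest, **paths)


def _sweep_regions(cfg: SimulationConfig, genes: list[_Gene]
                   ) -> list[RegulatoryFeature]:
    """Sweep intervals covering the first few density-enriched genes."""
    targets = [g for g in genes if g.role == "density"][:cfg.n_sweep_regions]
    if not targets:
        targets = genes[:cfg.n_sweep_regions]
    return [RegulatoryFeature(chrom=g.record.chrom,
                              start=max(1, g.record.start - 1000),
                              end=g.record.end + 1000,
                              feature_class="sweep_region",
                              name=f"sweep{i}")
            for i, g in enumerate(targets)]


def load_bundle(directory: str | Path) -> SimulatedBundle:
    """Re-open a bundle previously written by :func:`simulate_bundle`."""
    out = Path(directory)
    manifest = json.loads((out / "manifest.json").read_text())
    paths = {k: out / v for k, v in manifest["files"].items()}
    return SimulatedBundle(
        directory=out,
        truth_sites=pd.read_csv(out / "truth_sites.tsv", sep="\t",
                                dtype={"chrom": str},
                                keep_default_na=False),
        truth_genes=pd.read_csv(out / "truth_genes.tsv", sep="\t"),
        truth_traits=pd.read_csv(out / "truth_traits.tsv", sep="\t"),
        manifest=out / "manifest.json", **paths)


def verify_bundle(bundle: SimulatedBundle, **pipeline_kwargs) -> dict:
    """Run the real pipeline on a bundle and diff labels against truth.

    Returns a report with per-category agreement counts; the central
    closure property is 100% agreement under default settings.
    """
    from .pipeline import classify_bundle

    classified, verdict_reasons = classify_bundle(bundle, **pipeline_kwargs)
    got = {(c.site.chrom, c.site.pos): c for c in classified}
    report: dict[str, dict] = {}
    mismatches = []
    for row in bundle.truth_sites.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        cat = row.planted_category
        entry = report.setdefault(cat, {"planted": 0, "agree": 0})
        entry["planted"] += 1
        if row.filter_fate != "admitted":
            ok = (key not in got
                  and verdict_reasons.get(key) == row.filter_fate)
        else:
            c = got.get(key)
            ok = (c is not None and c.lineage == row.lineage
                  and c.category == row.category
                  and (c.extended_condition or "") == row.extended_condition)
        if ok:
            entry["agree"] += 1
        else:
            mismatches.append({"chrom": key[0], "pos": key[1],
                               "planted": cat,
                               "got": (got[key].lineage, got[key].category,
                                       got[key].extended_condition)
                               if key in got else "absent"})
    report["_mismatches"] = mismatches[:50]
    report["_n_mismatches"] = len(mismatches)
    return report
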