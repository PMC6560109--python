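"""Readers and writers for every external format the pipeline touches.

VCF is handled through pysam, GFF3 through gffutils, FASTA through
pyfaidx/Biopython, tabular inputs through pandas.  BED input (0-based,
half-open) is converted to the internal 1-based inclusive convention on read
and converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

from .model import (
    ArchaicGenotype,
    GeneRecord,
    RegulatoryFeature,
    SiteObservation,
    TraitAssociation,
    TranscriptModel,
    VALID_BASES,
    autosome_or_x,
)

logger = logging.getLogger("sncatalog")


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive interval."""
    if start >= end:
        raise ValueError(f"empty/invalid BED interval [{start}, {end})")
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open BED interval."""
    if start > end:
        raise ValueError(f"invalid interval {start}-{end}")
    return start - 1, end


# ---------------------------------------------------------------------------
# archaic VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfSiteRecord:
    """One biallelic (ref, alt) record after multi-allelic decomposition.

    Genotypes are stored at the base level, so an individual carrying a third
    allele keeps that base even in a record keyed by a different alt.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, ArchaicGenotype] = field(default_factory=dict)


@dataclass(frozen=True)
class VcfRow:
    """One raw (possibly multi-allelic) row, the writer-side representation.

    ``genotypes`` maps individual id to (allele1, allele2, DP, GQ, AD) where
    alleles are bases or None and AD is a per-allele tuple or None.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple] = field(default_factory=dict)


def read_archaic_vcf(
    path: str | Path,
    roster: Iterable[str],
    on_extra_sample: str = "error",
) -> Iterator[VcfSiteRecord]:
    """Stream biallelic records from a VCF 4.x file with GT:DP:GQ[:AD].

    Multi-allelic rows are decomposed into one record per alternative allele;
    the total number of (position, alt) pairs is preserved.  Missing DP/GQ
    are carried as 0.  Samples absent from the roster either raise or are
    skipped depending on ``on_extra_sample``.
    """
    roster = list(roster)
    if on_extra_sample not in ("error", "skip"):
        raise ValueError("on_extra_sample must be 'error' or 'skip'")
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        extra = [s for s in samples if s not in roster]
        if extra and on_extra_sample == "error":
            raise ValueError(f"samples not in roster: {extra}")
        missing = [s for s in roster if s not in samples]
        if missing:
            raise ValueError(f"roster individuals absent from VCF: {missing}")
        for n, rec in enumerate(vcf, start=1):
            try:
                yield from _decompose_record(rec, roster)
            except ValueError as exc:
                raise ValueError(f"malformed VCF record #{n} "
                                 f"({rec.chrom}:{rec.pos}): {exc}") from exc


def _decompose_record(rec, roster: list[str]) -> Iterator[VcfSiteRecord]:
    ref = rec.ref
    alts = rec.alts or ()
    if ref is None or any(a is None for a in alts):
        raise ValueError("missing REF/ALT")
    genotypes: dict[str, ArchaicGenotype] = {}
    for sample in roster:
        call = rec.samples[sample]
        gt = call.get("GT")
        alleles_here = (ref,) + tuple(alts)
        if gt is None or any(i is None for i in gt):
            a1 = a2 = None
        else:
            if len(gt) != 2:
                raise ValueError(f"non-diploid genotype for {sample}")
            a1, a2 = alleles_here[gt[0]], alleles_here[gt[1]]
        dp = call.get("DP")
        gq = call.get("GQ")
        ad = call.get("AD")
        if ad is not None and any(x is None for x in ad):
            ad = None
        genotypes[sample] = ArchaicGenotype(
            individual_id=sample,
            allele1=a1,
            allele2=a2,
            depth=int(dp) if dp is not None else 0,
            genotype_quality=int(gq) if gq is not None else 0,
            allelic_depths=tuple(int(x) for x in ad[:2]) if ad is not None else None,
        )
    for alt in alts:
        yield VcfSiteRecord(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                            genotypes=dict(genotypes))


def write_archaic_vcf(rows: Iterable[VcfRow], path: str | Path,
                      roster: Iterable[str],
                      contigs: Iterable[tuple[str, int]]) -> None:
    """Write raw (possibly multi-allelic) rows to an uncompressed VCF."""
    roster = list(roster)
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for sample in roster:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in rows:
            rec = out.new_record(contig=row.chrom, start=row.pos - 1,
                                 alleles=(row.ref,) + row.alts)
            rec.id = None
            alleles_here = (row.ref,) + row.alts
            for sample in roster:
                a1, a2, dp, gq, ad = row.genotypes[sample]
                if a1 is None or a2 is None:
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    rec.samples[sample]["GT"] = (alleles_here.index(a1),
                                                 alleles_here.index(a2))
                rec.samples[sample]["DP"] = dp
                rec.samples[sample]["GQ"] = gq
                if ad is not None:
                    padded = tuple(ad) + (0,) * (len(alleles_here) - len(ad))
                    rec.samples[sample]["AD"] = padded
            out.write(rec)


# ---------------------------------------------------------------------------
# human allele-count table
# ---------------------------------------------------------------------------

FREQ_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def read_frequency_table(path: str | Path) -> dict[tuple[str, int, str, str], tuple[int, int]]:
    """Read a TSV of per-site human reference/alternative allele counts.

    Returns a mapping (chrom, pos, ref, alt) -> (ref_count, alt_count).
    Rows with zero total count are skipped with a warning; duplicate keys are
    an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frequency table missing columns: {missing}")
    out: dict[tuple[str, int, str, str], tuple[int, int]] = {}
    n_zero = 0
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        rc, ac = int(row.ref_count), int(row.alt_count)
        if rc < 0 or ac < 0:
            raise ValueError(f"negative allele count at {key}")
        if rc + ac == 0:
            n_zero += 1
            continue
        if key in out:
            raise ValueError(f"duplicate frequency-table row for "
                             f"{key[0]}:{key[1]} {key[2]}>{key[3]}")
        out[key] = (rc, ac)
    if n_zero:
        logger.warning("frequency table: skipped %d rows with zero total count", n_zero)
    return out


def write_frequency_table(counts: dict[tuple[str, int, str, str], tuple[int, int]],
                          path: str | Path) -> None:
    rows = [(c, p, r, a, rc, ac) for (c, p, r, a), (rc, ac) in counts.items()]
    df = pd.DataFrame(rows, columns=FREQ_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ancestral-allele track
# ---------------------------------------------------------------------------

def read_ancestral_track(path: str | Path) -> dict[tuple[str, int], tuple[Optional[str], Optional[str]]]:
    """Read a TSV with columns chrom, pos, epo_allele, macaque_allele.

    '.' marks a missing allele.  Returns (chrom, pos) -> (epo, macaque).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "epo_allele", "macaque_allele"):
        if col not in df.columns:
            raise ValueError(f"ancestral track missing column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        epo = None if row.epo_allele in (".", None) else str(row.epo_allele)
        mac = None if row.macaque_allele in (".", None) else str(row.macaque_allele)
        out[(str(row.chrom), int(row.pos))] = (epo, mac)
    return out


def write_ancestral_track(track: dict[tuple[str, int], tuple[Optional[str], Optional[str]]],
                          path: str | Path) -> None:
    rows = [(c, p, e or ".", m or ".") for (c, p), (e, m) in track.items()]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "epo_allele", "macaque_allele"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(gff3_path: str | Path) -> list[GeneRecord]:
    """Read gene/mRNA/exon/CDS features from a GFF3 file.

    Transcripts whose CDS length is not a multiple of 3 are logged and
    skipped; CDS features without a parent transcript likewise.
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneRecord] = []
    for g in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        for t in db.children(g, featuretype="mRNA"):
            exons = tuple(sorted((f.start, f.end)
                                 for f in db.children(t, featuretype="exon")))
            cds = tuple(sorted((f.start, f.end)
                               for f in db.children(t, featuretype="CDS")))
            if not exons:
                exons = ((t.start, t.end),)
            model = TranscriptModel(transcript_id=t.id, exons=exons, cds=cds)
            if cds and model.cds_length % 3 != 0:
                logger.warning("transcript %s: CDS length %d not a multiple "
                               "of 3; skipped", t.id, model.cds_length)
                continue
            transcripts.append(model)
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(GeneRecord(gene_id=g.id, gene_name=name, chrom=g.seqid,
                                start=g.start, end=g.end, strand=g.strand,
                                transcripts=transcripts))
    n_orphans = sum(1 for f in db.features_of_type("CDS")
                    if not list(db.parents(f, featuretype="mRNA")))
    if n_orphans:
        logger.warning("GFF3: skipped %d CDS features without a parent "
                       "transcript", n_orphans)
    return genes


def write_gene_models(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as a minimal valid GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([g.chrom, "sncatalog", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                f"ID={g.gene_id};Name={g.gene_name}"]) + "\n")
            for t in g.transcripts:
                fh.write("\t".join([g.chrom, "sncatalog", "mRNA",
                                    str(t.start), str(t.end), ".", g.strand,
                                    ".", f"ID={t.transcript_id};Parent={g.gene_id}"]) + "\n")
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write("\t".join([g.chrom, "sncatalog", "exon", str(s),
                                        str(e), ".", g.strand, ".",
                                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]) + "\n")
                phase = 0
                for i, (s, e) in enumerate(t.cds if g.strand == "+" else t.cds[::-1], 1):
                    fh.write("\t".join([g.chrom, "sncatalog", "CDS", str(s),
                                        str(e), ".", g.strand, str(phase),
                                        f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"]) + "\n")
                    phase = (3 - ((e - s + 1 - phase) % 3)) % 3


# ---------------------------------------------------------------------------
# BED features, trait table
# ---------------------------------------------------------------------------

def read_bed_features(path: str | Path, feature_class: str) -> list[RegulatoryFeature]:
    """Read a BED4 file into 1-based inclusive RegulatoryFeatures."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            start, end = bed_to_internal(int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else "."
            feats.append(RegulatoryFeature(chrom=parts[0], start=start,
                                           end=end, feature_class=feature_class,
                                           name=name))
    return feats


def write_bed_features(feats: Iterable[RegulatoryFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in feats:
            s, e = internal_to_bed(f.start, f.end)
            fh.write(f"{f.chrom}\t{s}\t{e}\t{f.name}\n")


def read_trait_table(path: str | Path) -> list[TraitAssociation]:
    """Read trait-gene associations (TSV: trait, gene_id), de-duplicated."""
    df = pd.read_csv(path, sep="\t")
    for col in ("trait", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"trait table missing column {col!r}")
    seen = set()
    out = []
    for row in df.itertuples(index=False):
        pair = (str(row.trait), str(row.gene_id))
        if pair not in seen:
            seen.add(pair)
            out.append(TraitAssociation(trait_name=pair[0], gene_id=pair[1]))
    return out


def write_trait_table(assocs: Iterable[TraitAssociation], path: str | Path) -> None:
    df = pd.DataFrame([(a.trait_name, a.gene_id) for a in assocs],
                      columns=["trait", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# joining inputs into SiteObservations
# ---------------------------------------------------------------------------

def build_site_observations(
    counts: dict[tuple[str, int, str, str], tuple[int, int]],
    vcf_records: Iterable[VcfSiteRecord],
    ancestral: dict[tuple[str, int], tuple[Optional[str], Optional[str]]],
    restrict_chromosomes: bool = True,
    use_macaque_as_ancestral: bool = False,
) -> list[SiteObservation]:
    """Join allele counts, archaic genotypes and ancestral states by position.

    The human count table defines the biallelic site (ref, alt); archaic
    genotypes are attached by (chrom, pos) so that third-allele genotypes are
    kept at the base level.  The EPO allele sets the ancestral state when it
    matches ref or alt; otherwise the state stays unknown (with a tally) and
    the macaque base is recorded for the extended classification pathways.
    With ``use_macaque_as_ancestral`` the macaque base is promoted to the
    ancestral state when the EPO allele is missing.
    """
    geno_by_pos: dict[tuple[str, int], dict[str, ArchaicGenotype]] = {}
    for rec in vcf_records:
        geno_by_pos.setdefault((rec.chrom, rec.pos), {}).update(rec.genotypes)

    sites: list[SiteObservation] = []
    n_dropped_chrom = n_mismatch = n_nonsnv = 0
    for (chrom, pos, ref, alt), (rc, ac) in counts.items():
        if restrict_chromosomes and not autosome_or_x(chrom):
            n_dropped_chrom += 1
            continue
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
            n_nonsnv += 1
            continue
        epo, mac = ancestral.get((chrom, pos), (None, None))
        anc, src = "unknown", "none"
        if epo is not None:
            if epo == ref:
                anc, src = "ref", "alignment"
            elif epo == alt:
                anc, src = "alt", "alignment"
            else:
                n_mismatch += 1
        elif use_macaque_as_ancestral and mac is not None:
            if mac == ref:
                anc, src = "ref", "macaque"
            elif mac == alt:
                anc, src = "alt", "macaque"
        sites.append(SiteObservation(
            chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            ref_count=rc, alt_count=ac, ancestral=anc, ancestral_source=src,
            macaque_allele=mac,
            archaic_genotypes=geno_by_pos.get((chrom, pos), {}),
        ))
    if n_dropped_chrom:
        logger.info("dropped %d sites on non-autosome/X chromosomes", n_dropped_chrom)
    if n_nonsnv:
        logger.info("dropped %d non-SNV or non-biallelic rows", n_nonsnv)
    if n_mismatch:
        logger.info("%d sites with EPO allele matching neither ref nor alt "
                    "(ancestral set to unknown)", n_mismatch)
    return sites
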