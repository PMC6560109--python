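"""Minimal variant-consequence annotation against transcript models.

Assigns each site one record per overlapping transcript or regulatory
feature, VEP-style: coding classes by strand-aware codon substitution under
the standard genetic code, splice sites as the first/last two intronic
bases, UTRs relative to the CDS, upstream/downstream within a configurable
window (default 5,000 bp) of the transcript span, and TFBS / miRNA /
regulatory-element classes from user-supplied BED tracks.  Classes are not
mutually exclusive across transcripts; per-site summaries count each class
once per site.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .classification import ClassifiedSite
from .grantham import grantham_score, DELETERIOUS_CUTOFF
from .model import GeneRecord, RegulatoryFeature, SiteObservation, TranscriptModel

logger = logging.getLogger("sncatalog")

CONSEQUENCE_CLASSES = (
    "missense", "synonymous", "stop_gained", "stop_lost", "start_lost",
    "splice_site", "five_prime_utr", "three_prime_utr", "upstream",
    "downstream", "tfbs", "mirna", "regulatory_element", "intergenic",
    "intronic",
)

DEFAULT_WINDOW = 5000
SPLICE_BASES = 2


@dataclass(frozen=True)
class ConsequenceRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    transcript_id: Optional[str]
    consequence_class: str
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    grantham: Optional[int] = None
    external_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence_class!r}")
        if self.grantham is not None and self.consequence_class != "missense":
            raise ValueError("grantham score implies a missense record")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class GenomeSequence:
    """Thin wrapper over a pyfaidx.Fasta or an in-memory dict of sequences."""

    def __init__(self, source) -> None:
        self._source = source

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        import pyfaidx
        return cls(pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return str(self._source[chrom][start - 1:end]).upper()


class _TranscriptIndex:
    """Cached per-transcript CDS sequence and coordinate map."""

    def __init__(self, gene: GeneRecord, tx: TranscriptModel,
                 genome: GenomeSequence) -> None:
        self.gene = gene
        self.tx = tx
        cds = sorted(tx.cds)
        seq = "".join(genome.fetch(gene.chrom, s, e) for s, e in cds)
        positions: list[int] = []
        for s, e in cds:
            positions.extend(range(s, e + 1))
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
            positions = positions[::-1]
        self.cds_seq = seq
        self.cds_positions = {p: i for i, p in enumerate(positions)}
        protein = str(Seq(seq).translate()) if seq else ""
        self.translates_cleanly = (len(seq) % 3 == 0
                                   and "*" not in protein[:-1])


def _coding_consequence(idx: _TranscriptIndex, pos: int, alt: str
                        ) -> tuple[str, Optional[str], Optional[str], Optional[int]]:
    offset = idx.cds_positions[pos]
    codon_i, within = divmod(offset, 3)
    codon = idx.cds_seq[codon_i * 3:codon_i * 3 + 3]
    alt_base = alt if idx.gene.strand == "+" else str(Seq(alt).complement())
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous", ref_aa, alt_aa, None
    if codon_i == 0 and ref_aa == "M":
        return "start_lost", ref_aa, alt_aa, None
    if alt_aa == "*":
        return "stop_gained", ref_aa, alt_aa, None
    if ref_aa == "*":
        return "stop_lost", ref_aa, alt_aa, None
    return "missense", ref_aa, alt_aa, grantham_score(ref_aa, alt_aa)


class Annotator:
    """Annotates sites against gene models, a genome and regulatory tracks."""

    def __init__(self, genes: Sequence[GeneRecord], genome: GenomeSequence,
                 features: Sequence[RegulatoryFeature] = (),
                 window: int = DEFAULT_WINDOW) -> None:
        self.genome = genome
        self.window = window
        self._gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._feat_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._tx_cache: dict[str, _TranscriptIndex] = {}
        for g in genes:
            lo = max(1, g.start - window)
            self._gene_trees[g.chrom].addi(lo, g.end + window + 1, g)
        for f in features:
            self._feat_trees[f.chrom].addi(f.start, f.end + 1, f)

    def _tx_index(self, gene: GeneRecord, tx: TranscriptModel) -> _TranscriptIndex:
        key = tx.transcript_id
        if key not in self._tx_cache:
            self._tx_cache[key] = _TranscriptIndex(gene, tx, self.genome)
        return self._tx_cache[key]

    def annotate_site(self, site: SiteObservation) -> list[ConsequenceRecord]:
        chrom, pos = site.chrom, site.pos
        out: list[ConsequenceRecord] = []
        for iv in sorted(self._gene_trees.get(chrom, IntervalTree())[pos],
                         key=lambda iv: iv.data.gene_id):
            gene: GeneRecord = iv.data
            for tx in gene.transcripts:
                rec = self._annotate_transcript(site, gene, tx)
                if rec is not None:
                    out.append(rec)
        for iv in sorted(self._feat_trees.get(chrom, IntervalTree())[pos],
                         key=lambda iv: iv.data.name):
            f: RegulatoryFeature = iv.data
            out.append(ConsequenceRecord(
                chrom=chrom, pos=pos, ref=site.ref_allele, alt=site.alt_allele,
                gene_id=None, transcript_id=f.name,
                consequence_class=f.feature_class))
        if not out:
            out.append(ConsequenceRecord(
                chrom=chrom, pos=pos, ref=site.ref_allele, alt=site.alt_allele,
                gene_id=None, transcript_id=None,
                consequence_class="intergenic"))
        return out

    def _annotate_transcript(self, site: SiteObservation, gene: GeneRecord,
                             tx: TranscriptModel) -> Optional[ConsequenceRecord]:
        pos = site.pos
        base = dict(chrom=site.chrom, pos=pos, ref=site.ref_allele,
                    alt=site.alt_allele, gene_id=gene.gene_id,
                    transcript_id=tx.transcript_id)
        if pos < tx.start or pos > tx.end:
            # flanking classes, strand-aware
            if tx.start - self.window <= pos < tx.start:
                cls = "upstream" if gene.strand == "+" else "downstream"
            elif tx.end < pos <= tx.end + self.window:
                cls = "downstream" if gene.strand == "+" else "upstream"
            else:
                return None
            return ConsequenceRecord(consequence_class=cls, **base)

        in_exon = any(s <= pos <= e for s, e in tx.exons)
        cds = sorted(tx.cds)
        if in_exon and cds and any(s <= pos <= e for s, e in cds):
            idx = self._tx_index(gene, tx)
            if not idx.translates_cleanly:
                logger.warning("transcript %s fails translation sanity check; "
                               "intronic-level fallback", tx.transcript_id)
                return ConsequenceRecord(consequence_class="intronic", **base)
            cls, ref_aa, alt_aa, score = _coding_consequence(
                idx, pos, site.alt_allele)
            return ConsequenceRecord(consequence_class=cls, ref_aa=ref_aa,
                                     alt_aa=alt_aa, grantham=score, **base)
        if in_exon:
            if not cds:
                return ConsequenceRecord(consequence_class="intronic", **base)
            cds_lo, cds_hi = cds[0][0], cds[-1][1]
            if pos < cds_lo:
                cls = "five_prime_utr" if gene.strand == "+" else "three_prime_utr"
            else:
                cls = "three_prime_utr" if gene.strand == "+" else "five_prime_utr"
            return ConsequenceRecord(consequence_class=cls, **base)
        # intronic; splice sites are the first/last SPLICE_BASES of an intron
        exons = sorted(tx.exons)
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if e1 < pos < s2:
                if pos - e1 <= SPLICE_BASES or s2 - pos <= SPLICE_BASES:
                    return ConsequenceRecord(consequence_class="splice_site", **base)
                break
        return ConsequenceRecord(consequence_class="intronic", **base)


def annotate_sites(sites: Iterable[SiteObservation], annotator: Annotator
                   ) -> list[ConsequenceRecord]:
    out: list[ConsequenceRecord] = []
    for s in sites:
        out.extend(annotator.annotate_site(s))
    return out


def read_precomputed_annotation(path) -> list[ConsequenceRecord]:
    """Load a precomputed VEP-style annotation TSV instead of the internal
    annotator; the two paths are never mixed within a run."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    recs = []
    for row in df.itertuples(index=False):
        recs.append(ConsequenceRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene_id=getattr(row, "gene_id", None) or None,
            transcript_id=getattr(row, "transcript_id", None) or None,
            consequence_class=row.consequence_class,
            ref_aa=getattr(row, "ref_aa", None) or None,
            alt_aa=getattr(row, "alt_aa", None) or None,
            grantham=int(row.grantham) if getattr(row, "grantham", None)
            and not pd.isna(row.grantham) else None,
            external_scores={k: float(getattr(row, k)) for k in
                             ("sift", "polyphen", "cadd", "gwava")
                             if hasattr(row, k) and not pd.isna(getattr(row, k))},
        ))
    return recs


# ---------------------------------------------------------------------------
# deleteriousness flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeleteriousnessRules:
    """Published thresholds; external scores are consumed, never computed."""

    grantham_cutoff: int = DELETERIOUS_CUTOFF  # strictly greater
    sift_max: float = 0.05                     # strictly smaller
    polyphen_min: float = 0.908                # strictly greater
    cadd_top_n: Optional[int] = None
    gwava_top_n: Optional[int] = None


def flag_deleterious(records: Sequence[ConsequenceRecord],
                     rules: DeleteriousnessRules = DeleteriousnessRules()
                     ) -> list[ConsequenceRecord]:
    """Records flagged as putatively deleterious under any supplied score."""
    flagged: dict[int, ConsequenceRecord] = {}
    for i, r in enumerate(records):
        if r.grantham is not None and r.grantham > rules.grantham_cutoff:
            flagged[i] = r
        sift = r.external_scores.get("sift")
        if sift is not None and sift < rules.sift_max:
            flagged[i] = r
        poly = r.external_scores.get("polyphen")
        if poly is not None and poly > rules.polyphen_min:
            flagged[i] = r
    for score_name, top_n in (("cadd", rules.cadd_top_n),
                              ("gwava", rules.gwava_top_n)):
        if top_n is None:
            continue
        scored = [(r.external_scores[score_name], i) for i, r in enumerate(records)
                  if score_name in r.external_scores]
        for _, i in sorted(scored, reverse=True)[:top_n]:
            flagged[i] = records[i]
    return [flagged[i] for i in sorted(flagged)]


# ---------------------------------------------------------------------------
# catalog summary (the headline count table)
# ---------------------------------------------------------------------------

SUMMARY_ROWS = (
    ("All", None),
    ("Non-synonymous", {"missense"}),
    ("Synonymous", {"synonymous"}),
    ("Start/stop", {"start_lost", "stop_gained", "stop_lost"}),
    ("Splice site", {"splice_site"}),
    ("TFBS", {"tfbs"}),
    ("Upstream", {"upstream"}),
    ("5' UTR", {"five_prime_utr"}),
    ("3' UTR", {"three_prime_utr"}),
    ("Downstream", {"downstream"}),
    ("miRNA", {"mirna"}),
    ("Regulatory element", {"regulatory_element"}),
)

SUMMARY_COLUMNS = ("fixed_human", "hf_human", "extended_human",
                   "fixed_archaic", "hf_archaic", "extended_archaic")


def _column_membership(c: ClassifiedSite) -> list[str]:
    """Summary columns a classified site contributes to.

    Fixed changes are a subset of HF changes, so a fixed site counts in both
    its fixed and HF columns; extended is a separate tally.
    """
    if c.lineage not in ("human", "archaic"):
        return []
    suffix = c.lineage
    if c.category == "fixed":
        return [f"fixed_{suffix}", f"hf_{suffix}"]
    if c.category == "high_frequency":
        return [f"hf_{suffix}"]
    if c.category == "extended":
        return [f"extended_{suffix}"]
    return []


def summarize_catalog(classified: Sequence[ClassifiedSite],
                      records: Sequence[ConsequenceRecord]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count table in the headline-table shape plus per-chromosome
    missense/synonymous ratios of HF changes per lineage.

    Returns (count_table, ratio_table); undefined ratios (zero synonymous
    changes) are reported as missing values, not infinities.
    """
    classes_by_site: dict[tuple, set[str]] = defaultdict(set)
    for r in records:
        classes_by_site[r.site_key].add(r.consequence_class)

    table = pd.DataFrame(0, index=[r for r, _ in SUMMARY_ROWS],
                         columns=list(SUMMARY_COLUMNS))
    per_chrom: dict[tuple[str, str, str], int] = defaultdict(int)
    for c in classified:
        cols = _column_membership(c)
        if not cols:
            continue
        site_classes = classes_by_site.get(c.site.key, set())
        for col in cols:
            table.loc["All", col] += 1
            for row_name, members in SUMMARY_ROWS[1:]:
                if site_classes & members:
                    table.loc[row_name, col] += 1
        if c.category in ("fixed", "high_frequency"):  # HF includes fixed
            for cls in ("missense", "synonymous"):
                if cls in site_classes:
                    per_chrom[(c.site.chrom, c.lineage, cls)] += 1

    chroms = sorted({k[0] for k in per_chrom})
    ratio_rows = []
    for chrom in chroms:
        row = {"chrom": chrom}
        for lineage in ("human", "archaic"):
            mis = per_chrom.get((chrom, lineage, "missense"), 0)
            syn = per_chrom.get((chrom, lineage, "synonymous"), 0)
            row[f"{lineage}_missense"] = mis
            row[f"{lineage}_synonymous"] = syn
            row[f"{lineage}_ratio"] = mis / syn if syn > 0 else float("nan")
        ratio_rows.append(row)
    ratios = pd.DataFrame(ratio_rows)
    if not ratios.empty:
        ratios = ratios.set_index("chrom")
    return table, ratios
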