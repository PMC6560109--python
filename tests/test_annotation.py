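"""Consequence annotation against toy transcript models: codon arithmetic,
strand mirroring, window classes, deleteriousness flags and the summary
table."""

import pytest

from sncatalog.annotation import (Annotator, ConsequenceRecord,
                                  DeleteriousnessRules, GenomeSequence,
                                  flag_deleterious, summarize_catalog)
from sncatalog.classification import ClassifiedSite
from sncatalog.model import GeneRecord, RegulatoryFeature, TranscriptModel
from tests.conftest import make_site

# Toy gene on "+": 5'UTR 1..10, CDS 11..31 + 35..46 (intron 32..34, 33 bp
# CDS = 11 codons), 3'UTR 47..60.  Coding sequence chosen by hand:
#   ATG CTG CGG AAA TTT GGG CC|C ACG TAC GAT TAA
CODING = "ATGCTGCGGAAATTTGGGCCCACGTACGATTAA"


def _plus_genome():
    seq = ["A"] * 300
    seq[10:31] = CODING[:21]
    seq[34:46] = CODING[21:]
    return "".join(seq)


def _plus_gene():
    tx = TranscriptModel("t1", exons=((1, 31), (35, 60)),
                         cds=((11, 31), (35, 46)))
    return GeneRecord("g1", "g1", "1", 1, 60, "+", [tx])


def _revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def _minus_genome():
    # same transcript mirrored: genomic left-to-right holds revcomp(CODING)
    seq = ["A"] * 300
    rc = _revcomp(CODING)
    seq[10:22] = rc[:12]   # CDS2 part (3' end of coding seq)
    seq[25:46] = rc[12:]
    return "".join(seq)


def _minus_gene():
    tx = TranscriptModel("t1m", exons=((1, 22), (26, 60)),
                         cds=((11, 22), (26, 46)))
    return GeneRecord("g1m", "g1m", "1", 1, 60, "-", [tx])


def annotate(gene, genome_str, pos, alt, ref=None, features=()):
    ann = Annotator([gene], GenomeSequence({"1": genome_str}), features)
    site = make_site(2500, ref=ref or genome_str[pos - 1], alt=alt,
                     pos=pos, chrom="1")
    return ann.annotate_site(site)


class TestCodingClasses:
    def test_missense_with_grantham(self):
        # codon 2 is CTG (Leu) at positions 14-16; CTG->CGG is Leu->Arg
        recs = annotate(_plus_gene(), _plus_genome(), 15, "G")
        (r,) = [r for r in recs if r.gene_id == "g1"]
        assert (r.consequence_class, r.ref_aa, r.alt_aa, r.grantham) == \
            ("missense", "L", "R", 102)

    def test_synonymous_third_position(self):
        # codon 2 CTG: third position 16, CTG->CTA both Leu
        recs = annotate(_plus_gene(), _plus_genome(), 16, "A")
        (r,) = [r for r in recs if r.gene_id == "g1"]
        assert (r.consequence_class, r.grantham) == ("synonymous", None)

    def test_stop_gained_and_start_lost(self):
        # codon 7 CCC (Pro) at 29-31: C->A at the third position stays Pro
        recs = annotate(_plus_gene(), _plus_genome(), 31, "A")
        (r,) = [r for r in recs if r.gene_id == "g1"]
        assert r.consequence_class == "synonymous"
        # start codon ATG at 11-13: A->C kills the start
        recs = annotate(_plus_gene(), _plus_genome(), 11, "C")
        (r,) = [r for r in recs if r.gene_id == "g1"]
        assert r.consequence_class == "start_lost"
        # stop codon TAA at 44-46: A->C turns stop into Tyr codon
        recs = annotate(_plus_gene(), _plus_genome(), 45, "C")
        (r,) = [r for r in recs if r.gene_id == "g1"]
        assert r.consequence_class == "stop_lost"
        # codon 9 TAC (Tyr) at 38-40: C->A gives TAA (stop)
        recs = annotate(_plus_gene(), _plus_genome(), 40, "A")
        (r,) = [r for r in recs if r.gene_id == "g1"]
        assert r.consequence_class == "stop_gained"

    def test_strand_mirror_gives_same_classes(self):
        """The same coding change on a reverse-strand copy of the gene
        yields the same consequence class."""
        # + strand: codon 2 CTG->CGG missense at genomic pos 15 (alt G)
        plus = annotate(_plus_gene(), _plus_genome(), 15, "G")
        # - strand: coding position 5 maps to genomic pos 46-4=42; the
        # coding-strand alt G is genomic complement C
        minus = annotate(_minus_gene(), _minus_genome(), 42, "C")
        rp = [r for r in plus if r.gene_id][0]
        rm = [r for r in minus if r.gene_id][0]
        assert (rp.consequence_class, rp.ref_aa, rp.alt_aa, rp.grantham) == \
            (rm.consequence_class, rm.ref_aa, rm.alt_aa, rm.grantham)


class TestNonCodingClasses:
    @pytest.mark.parametrize("pos,expected", [
        (32, "splice_site"), (33, "splice_site"),  # first 2 intronic bases
        (5, "five_prime_utr"), (50, "three_prime_utr"),
    ])
    def test_classes(self, pos, expected):
        recs = annotate(_plus_gene(), _plus_genome(), pos, "C")
        assert [r.consequence_class for r in recs if r.gene_id] == [expected]

    def test_longer_intron_has_interior(self):
        tx = TranscriptModel("t2", exons=((1, 31), (132, 160)),
                             cds=((11, 31), (132, 143)))
        gene = GeneRecord("g2", "g2", "1", 1, 160, "+", [tx])
        seq = ["A"] * 400
        seq[10:31] = CODING[:21]
        seq[131:143] = CODING[21:]
        genome = "".join(seq)
        assert [r.consequence_class for r in
                annotate(gene, genome, 33, "C") if r.gene_id] == ["splice_site"]
        assert [r.consequence_class for r in
                annotate(gene, genome, 80, "C") if r.gene_id] == ["intronic"]
        assert [r.consequence_class for r in
                annotate(gene, genome, 130, "C") if r.gene_id] == ["splice_site"]

    def test_window_arithmetic(self):
        """4,999 bp upstream is 'upstream'; 5,001 bp is intergenic."""
        tx = TranscriptModel("t3", exons=((10_000, 10_100),), cds=())
        gene = GeneRecord("g3", "g3", "1", 10_000, 10_100, "+", [tx])
        genome = "A" * 20_000
        up = annotate(gene, genome, 10_000 - 4_999, "C")
        assert [r.consequence_class for r in up] == ["upstream"]
        far = annotate(gene, genome, 10_000 - 5_001, "C")
        assert [r.consequence_class for r in far] == ["intergenic"]
        down = annotate(gene, genome, 10_100 + 100, "C")
        assert [r.consequence_class for r in down] == ["downstream"]

    def test_regulatory_features(self):
        # feature beyond the flanking window: only the feature class applies
        feats = [RegulatoryFeature("1", 6000, 6020, "tfbs", "f1")]
        genome = _plus_genome() + "A" * 7000
        recs = annotate(_plus_gene(), genome, 6010, "C", features=feats)
        assert [r.consequence_class for r in recs] == ["tfbs"]


class TestDeleterious:
    def _rec(self, grantham=None, cls="missense", **scores):
        return ConsequenceRecord(chrom="1", pos=1, ref="A", alt="G",
                                 gene_id="g", transcript_id="t",
                                 consequence_class=cls,
                                 ref_aa="L" if cls == "missense" else None,
                                 alt_aa="R" if cls == "missense" else None,
                                 grantham=grantham, external_scores=scores)

    def test_grantham_cutoff_is_strict(self):
        flagged = flag_deleterious([self._rec(181), self._rec(180)])
        assert [r.grantham for r in flagged] == [181]

    def test_unscored_records_never_flagged(self):
        assert flag_deleterious([self._rec(None)]) == []
        assert flag_deleterious([]) == []

    def test_external_scores(self):
        recs = [self._rec(None, sift=0.04), self._rec(None, sift=0.05),
                self._rec(None, polyphen=0.95), self._rec(None, cadd=30.0),
                self._rec(None, cadd=10.0)]
        flagged = flag_deleterious(recs, DeleteriousnessRules(cadd_top_n=1))
        assert flagged == [recs[0], recs[2], recs[3]]


class TestSummary:
    def _classified(self, pos, lineage, category, chrom="1"):
        site = make_site(2500, pos=pos, chrom=chrom)
        cond = "a" if category == "extended" else None
        return ClassifiedSite(site=site, lineage=lineage, category=category,
                              extended_condition=cond, states={},
                              derived_allele="G", human_derived_freq=0.5)

    def _rec(self, pos, cls, chrom="1"):
        return ConsequenceRecord(chrom=chrom, pos=pos, ref="A", alt="G",
                                 gene_id="g", transcript_id="t",
                                 consequence_class=cls)

    def test_fixed_counts_into_hf_column(self):
        classified = [self._classified(1, "human", "fixed"),
                      self._classified(2, "human", "high_frequency"),
                      self._classified(3, "human", "extended")]
        records = [self._rec(p, "missense") for p in (1, 2, 3)]
        table, _ = summarize_catalog(classified, records)
        assert table.loc["All", "fixed_human"] == 1
        assert table.loc["All", "hf_human"] == 2  # fixed is a subset of HF
        assert table.loc["All", "extended_human"] == 1
        assert table.loc["Non-synonymous", "hf_human"] == 2

    def test_every_fixed_cell_at_most_hf_cell(self, pipeline_results):
        table = pipeline_results["summary_table"]
        for lineage in ("human", "archaic"):
            assert (table[f"fixed_{lineage}"] <= table[f"hf_{lineage}"]).all()

    def test_chromosome_ratio(self):
        classified = [self._classified(i, "human", "high_frequency", "21")
                      for i in range(1, 12)]
        records = [self._rec(i, "missense", "21") for i in range(1, 8)] + \
            [self._rec(i, "synonymous", "21") for i in range(8, 12)]
        _, ratios = summarize_catalog(classified, records)
        assert ratios.loc["21", "human_ratio"] == pytest.approx(1.75)

    def test_zero_synonymous_ratio_is_missing(self):
        classified = [self._classified(1, "human", "high_frequency")]
        records = [self._rec(1, "missense")]
        _, ratios = summarize_catalog(classified, records)
        import math
        assert math.isnan(ratios.loc["1", "human_ratio"])
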