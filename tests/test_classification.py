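"""Lineage/category classification: the defining predicates, polarity
handling, oracle equivalence on random sites, exclusivity and monotonicity."""

import numpy as np
import pytest

from sncatalog.classification import (ClassificationThresholds, classify_site,
                                      archaic_state, polarize)
from sncatalog.model import SiteObservation
from tests.conftest import (COHORT, make_genotype, make_site,
                            states_to_genotypes, verdicts_for)

T = ClassificationThresholds()
ROSTER = ("Denisovan", "AltaiNeanderthal", "VindijaNeanderthal")
DEN, ALT, VIN = ROSTER


def classify(site):
    return classify_site(site, verdicts_for(site), T, roster=ROSTER)


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def test_polarize_ancestral_ref():
    s = make_site(9995, total=10000)
    p = polarize(s)
    assert (p.derived_allele, p.derived_freq) == ("G", 0.9995)


def test_polarize_ancestral_alt_flips():
    """Ancestral = alt: the reference allele is the derived one."""
    s = SiteObservation(chrom="1", pos=100, ref_allele="A", alt_allele="G",
                        ref_count=5, alt_count=9995, ancestral="alt",
                        ancestral_source="alignment")
    p = polarize(s)
    assert (p.derived_allele, p.derived_count, p.derived_freq) == ("A", 5, 0.0005)


def test_polarize_unknown_ancestral_undefined():
    s = make_site(5000, ancestral="unknown", macaque="A")
    assert polarize(s).derived_freq is None


@pytest.mark.parametrize("a1,a2,expected", [
    ("A", "A", "ancestral_hom"), ("G", "G", "derived_hom"),
    ("A", "G", "heterozygous"), ("A", "T", "other_allele"),
    ("T", "T", "other_allele"),
])
def test_archaic_state(a1, a2, expected):
    g = make_genotype("Denisovan", a1, a2)
    assert archaic_state(g, "A", "G") == expected


def test_failed_genotype_is_missing_state():
    g = make_genotype("Denisovan", "A", "A", dp=2)
    assert archaic_state(g, "A", "G", passed=False) == "missing"


# ---------------------------------------------------------------------------
# category examples
# ---------------------------------------------------------------------------

def _site_with_states(derived_count, states, **kwargs):
    return make_site(derived_count, genotypes=states_to_genotypes(states),
                     **kwargs)


@pytest.mark.parametrize("d,states,expected", [
    # fixed: ancestral absent from humans, two of three archaics ancestral
    (COHORT, {DEN: "ancestral_hom", VIN: "ancestral_hom", ALT: "derived_hom"},
     ("human", "fixed", None)),
    # HF: Denisovan + one Neanderthal ancestral
    (int(0.95 * COHORT), {DEN: "ancestral_hom", VIN: "ancestral_hom",
                          ALT: "missing"}, ("human", "high_frequency", None)),
    # extended (a): incomplete genotypes, reliable ones ancestral
    (int(0.95 * COHORT), {DEN: "missing", VIN: "ancestral_hom",
                          ALT: "missing"}, ("human", "extended", "a")),
    # extended (b): a third allele, nobody carries the derived allele
    (int(0.95 * COHORT), {DEN: "other_allele", VIN: "ancestral_hom",
                          ALT: "ancestral_hom"}, ("human", "extended", "b")),
    # extended (c): Denisovan ancestral, Neanderthals derived
    (int(0.95 * COHORT), {DEN: "ancestral_hom", VIN: "derived_hom",
                          ALT: "derived_hom"}, ("human", "extended", "c")),
    # below the 90% threshold: nothing
    (int(0.89 * COHORT), {DEN: "ancestral_hom", VIN: "ancestral_hom",
                          ALT: "ancestral_hom"}, ("none", "none", None)),
    # heterozygous archaic counts as carrying the derived allele (strict)
    (int(0.95 * COHORT), {DEN: "heterozygous", VIN: "ancestral_hom",
                          ALT: "ancestral_hom"}, ("none", "none", None)),
    # archaic fixed: all three derived, humans ancestral > 99.999%
    (0, {DEN: "derived_hom", VIN: "derived_hom", ALT: "derived_hom"},
     ("archaic", "fixed", None)),
    # archaic HF: < 1% derived in humans, two archaics derived
    (25, {DEN: "derived_hom", VIN: "derived_hom", ALT: "missing"},
     ("archaic", "high_frequency", None)),
    # archaic HF with mid-frequency humans: nothing
    (2500, {DEN: "derived_hom", VIN: "derived_hom", ALT: "derived_hom"},
     ("none", "none", None)),
])
def test_classification_examples(d, states, expected):
    c = classify(_site_with_states(d, states))
    assert (c.lineage, c.category, c.extended_condition) == expected


def test_fixed_requires_zero_ancestral_count():
    """One remaining ancestral copy demotes fixed to high-frequency."""
    states = {DEN: "ancestral_hom", VIN: "ancestral_hom", ALT: "derived_hom"}
    c = classify(_site_with_states(COHORT - 1, states))
    assert (c.lineage, c.category) == ("human", "high_frequency")


def test_extended_d_macaque_pathway():
    """Unknown ancestral: macaque allele carried by all three archaics and
    >90% of humans carry the other allele."""
    gts = states_to_genotypes({DEN: "ancestral_hom", VIN: "ancestral_hom",
                               ALT: "ancestral_hom"})
    s = make_site(int(0.95 * COHORT), ancestral="unknown", macaque="A",
                  genotypes=gts)
    c = classify(s)
    assert (c.lineage, c.category, c.extended_condition) == ("human", "extended", "d")


def test_extended_archaic_macaque_pathway():
    """Unknown ancestral, macaque equals the major human allele, two
    archaics carry the minor allele."""
    gts = states_to_genotypes({DEN: "derived_hom", VIN: "derived_hom",
                               ALT: "ancestral_hom"})
    s = make_site(30, ancestral="unknown", macaque="A", genotypes=gts)
    c = classify(s)
    assert (c.lineage, c.category, c.extended_condition) == (
        "archaic", "extended", "macaque_match")


def test_lenient_mode_counts_heterozygotes_as_ancestral():
    states = {DEN: "heterozygous", VIN: "ancestral_hom", ALT: "ancestral_hom"}
    site = _site_with_states(int(0.95 * COHORT), states)
    lenient = ClassificationThresholds(lenient_ancestral=True)
    c = classify_site(site, verdicts_for(site), lenient, roster=ROSTER)
    assert (c.lineage, c.category) == ("human", "high_frequency")


def test_extended_c_exactly_one_flag():
    states = {DEN: "ancestral_hom", VIN: "derived_hom", ALT: "derived_hom"}
    site = _site_with_states(int(0.95 * COHORT), states)
    strict_c = ClassificationThresholds(extended_c_exactly_one=True)
    c = classify_site(site, verdicts_for(site), strict_c, roster=ROSTER)
    assert (c.category, c.extended_condition) != ("extended", "c")


# ---------------------------------------------------------------------------
# brute-force oracle over random sites
# ---------------------------------------------------------------------------

def oracle_classify(site, verdicts, t=T):
    """Direct predicate-by-predicate restatement of every category."""
    def state(ind, anc, der):
        g = site.archaic_genotypes.get(ind)
        if g is None or g.is_missing or not verdicts[ind].passed:
            return "missing"
        pair = {g.allele1, g.allele2}
        if not pair <= {anc, der}:
            return "other_allele"
        if pair == {anc}:
            return "ancestral_hom"
        if pair == {der}:
            return "derived_hom"
        return "heterozygous"

    def anc_carrier(st):
        return st == "ancestral_hom"

    def der_carrier(st):
        return st in ("derived_hom", "heterozygous")

    nean = [ALT, VIN]
    if site.ancestral == "unknown":
        mac = site.macaque_allele
        if mac in (site.ref_allele, site.alt_allele):
            der = site.alt_allele if mac == site.ref_allele else site.ref_allele
            d = site.alt_count if der == site.alt_allele else site.ref_count
            f = d / site.human_total_count
            sts = {i: state(i, mac, der) for i in ROSTER}
            if f > t.hf_human_min and all(sts[i] == "ancestral_hom" for i in ROSTER):
                return ("human", "extended", "d")
            if (f < t.archaic_hf_human_derived_max
                    and sum(der_carrier(sts[i]) for i in ROSTER) >= 2):
                return ("archaic", "extended", "macaque_match")
        return ("none", "none", None)

    anc = site.ancestral_allele
    der = site.derived_allele
    d = site.human_derived_count
    f = d / site.human_total_count
    sts = {i: state(i, anc, der) for i in ROSTER}
    if (site.human_total_count - d) == 0 and \
            sum(anc_carrier(sts[i]) for i in ROSTER) >= 2:
        return ("human", "fixed", None)
    if f > t.hf_human_min:
        if anc_carrier(sts[DEN]) and any(anc_carrier(sts[n]) for n in nean):
            return ("human", "high_frequency", None)
        present = {i: sts[i] for i in ROSTER if sts[i] != "missing"}
        if present and len(present) < 3 and all(
                anc_carrier(s) for s in present.values()):
            return ("human", "extended", "a")
        if present and any(s == "other_allele" for s in present.values()) \
                and all(s == "other_allele" or anc_carrier(s)
                        for s in present.values()):
            return ("human", "extended", "b")
        if anc_carrier(sts[DEN]) and any(der_carrier(sts[n]) for n in nean):
            return ("human", "extended", "c")
        return ("none", "none", None)
    if (1 - f) > t.archaic_fixed_human_ancestral_min and \
            all(der_carrier(sts[i]) for i in ROSTER):
        return ("archaic", "fixed", None)
    if f < t.archaic_hf_human_derived_max and \
            sum(der_carrier(sts[i]) for i in ROSTER) >= 2:
        return ("archaic", "high_frequency", None)
    return ("none", "none", None)


def random_site(rng):
    bases = ["A", "C", "G", "T"]
    ref, alt = rng.choice(bases, size=2, replace=False)
    third = next(b for b in bases if b not in (ref, alt))
    anc = ["ref", "alt", "unknown"][int(rng.integers(3))]
    mac = [ref, alt, third, None][int(rng.integers(4))]
    total = COHORT
    # mixture concentrated around the decision boundaries
    u = rng.random()
    if u < 0.3:
        d = int(rng.integers(0, 60))
    elif u < 0.6:
        d = total - int(rng.integers(0, 60))
    elif u < 0.8:
        d = int(rng.choice([int(0.9 * total), int(0.9 * total) + 1,
                            total - 1, total, 50, 51]))
    else:
        d = int(rng.integers(0, total + 1))
    gts = {}
    for ind in ROSTER:
        kind = rng.integers(6)
        pairs = [(ref, ref), (alt, alt), (ref, alt), (third, third),
                 (ref, third), (None, None)]
        a1, a2 = pairs[int(kind)]
        dp = int(rng.integers(0, 120))
        gq = int(rng.integers(0, 100))
        gts[ind] = make_genotype(ind, a1, a2, dp=dp, gq=gq,
                                 ad=(30, 10) if a1 != a2 and a1 and rng.random() < 0.5
                                 else None)
    if anc == "unknown":
        return make_site(d, ref=ref, alt=alt, ancestral="unknown",
                         macaque=mac, genotypes=gts, total=total)
    return make_site(d, ref=ref, alt=alt, ancestral=anc, macaque=mac,
                     genotypes=gts, total=total)


def test_classifier_agrees_with_oracle_on_random_sites(rng):
    """10,000 random sites: first-match classification equals an
    independent predicate-by-predicate oracle."""
    for i in range(10_000):
        s = random_site(rng)
        v = verdicts_for(s)
        c = classify_site(s, v, T, roster=ROSTER)
        assert (c.lineage, c.category, c.extended_condition) == \
            oracle_classify(s, v), (i, vars(s))


def test_every_site_gets_exactly_one_label(rng):
    """Exclusivity: one (lineage, category) pair or none, never both
    lineages."""
    for _ in range(2000):
        s = random_site(rng)
        v = verdicts_for(s)
        c = classify_site(s, v, T, roster=ROSTER)
        assert c.lineage in ("human", "archaic", "none")
        assert (c.category == "none") == (c.lineage == "none")


def test_lowering_hf_threshold_is_monotone(rng):
    """Lowering hf_human_min never removes a site from the human
    fixed-or-HF set."""
    lower = ClassificationThresholds(hf_human_min=0.85)
    for _ in range(2000):
        s = random_site(rng)
        v = verdicts_for(s)
        base_c = classify_site(s, v, T, roster=ROSTER)
        if base_c.lineage == "human" and base_c.category in (
                "fixed", "high_frequency"):
            low_c = classify_site(s, v, lower, roster=ROSTER)
            assert low_c.lineage == "human"
            assert low_c.category in ("fixed", "high_frequency")
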