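"""Allele polarization and lineage/category classification of sites.

Every admitted site is assigned to at most one (lineage, category) pair:

Human lineage (derived-allele frequency f in present-day humans):

* ``fixed`` — the ancestral allele is absent from the human cohort (ancestral
  count = 0, hence f = 1) and at least two of the three archaics carry the
  ancestral allele, allowing for human gene flow into Neanderthals.
* ``high_frequency`` — f > 0.90 and the Denisovan plus at least one
  Neanderthal carry the ancestral allele.
* ``extended`` — f > 0.90 under one of four relaxed-evidence conditions:
  (a) not all archaics have reliable genotypes but those that do carry the
  ancestral allele; (b) some archaic carries a third allele, identical to
  neither the human-derived nor the ancestral allele, and no archaic carries
  the derived allele; (c) the Denisovan carries the ancestral allele while a
  Neanderthal carries a derived allele (gene flow from humans into
  Neanderthals); (d) the ancestral allele is unknown, but the macaque
  reference base is identical to the allele carried by all three archaics,
  and more than 90% of humans carry the other allele.

Archaic lineage (mirrored):

* ``fixed`` — all three archaics carry the derived allele while humans carry
  the ancestral allele at more than 99.999% (derived frequency < 1e-5).
* ``high_frequency`` — derived frequency below 1% in humans while at least
  two archaic individuals carry the derived allele.
* ``extended`` — the ancestral allele is unknown, the macaque base equals
  the major human allele (frequency > 99%), and at least two archaics carry
  the minor, non-human allele.

"Carries the ancestral allele" defaults to homozygous-ancestral (strict
mode); a heterozygous archaic then counts as carrying the derived allele.
In lenient mode a heterozygote counts as carrying the ancestral allele.
Fixed sites also satisfy the high-frequency predicates, so summaries report
the HF tally as fixed + HF (fixed changes are a subset of HF changes); the
per-site label keeps the most specific category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .filtering import FilterVerdict
from .model import ArchaicGenotype, NEANDERTHALS, SiteObservation

ARCHAIC_STATES = ("ancestral_hom", "derived_hom", "heterozygous",
                  "other_allele", "missing")
EXTENDED_CONDITIONS = ("a", "b", "c", "d", "macaque_match")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Frequency thresholds and interpretation switches.

    All frequency comparisons are strict, matching the defining phrases
    ("more than 90%", "more than 99.999%", "less than 1%").
    """

    hf_human_min: float = 0.90
    archaic_fixed_human_ancestral_min: float = 0.99999
    archaic_hf_human_derived_max: float = 0.01
    lenient_ancestral: bool = False
    extended_c_exactly_one: bool = False

    def __post_init__(self) -> None:
        for v in (self.hf_human_min, self.archaic_fixed_human_ancestral_min,
                  self.archaic_hf_human_derived_max):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.hf_human_min <= self.archaic_hf_human_derived_max:
            raise ValueError("human HF and archaic HF frequency ranges overlap")


@dataclass(frozen=True)
class Polarization:
    """Outcome of polarizing a site against its ancestral state."""

    derived_allele: Optional[str]
    derived_count: Optional[int]
    total_count: int
    derived_freq: Optional[float]


@dataclass(frozen=True)
class ClassifiedSite:
    site: SiteObservation
    lineage: str  # human, archaic, none
    category: str  # fixed, high_frequency, extended, none
    extended_condition: Optional[str] = None
    states: Mapping[str, str] = field(default_factory=dict)
    derived_allele: Optional[str] = None
    human_derived_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.extended_condition is not None) != (self.category == "extended"):
            raise ValueError("extended_condition is set iff category is extended")


def polarize(s: SiteObservation) -> Polarization:
    """Derived-allele identity and human derived frequency.

    With an unknown ancestral state the frequency is undefined and the site
    is only eligible for the macaque-based extended pathways.
    """
    total = s.human_total_count
    if s.ancestral == "unknown":
        return Polarization(None, None, total, None)
    derived = s.derived_allele
    count = s.human_derived_count
    return Polarization(derived, count, total, count / total)


def archaic_state(g: Optional[ArchaicGenotype], ancestral: str, derived: str,
                  passed: bool = True) -> str:
    """Per-individual carrier state relative to the (ancestral, derived) pair."""
    if g is None or g.is_missing or not passed:
        return "missing"
    a1, a2 = g.alleles
    known = {ancestral, derived}
    if a1 not in known or a2 not in known:
        return "other_allele"
    if a1 == a2:
        return "ancestral_hom" if a1 == ancestral else "derived_hom"
    return "heterozygous"


def compute_states(s: SiteObservation, verdicts: Mapping[str, FilterVerdict],
                   ancestral: str, derived: str, roster) -> dict[str, str]:
    out = {}
    for ind in roster:
        g = s.archaic_genotypes.get(ind)
        passed = ind in verdicts and verdicts[ind].passed
        out[ind] = archaic_state(g, ancestral, derived, passed)
    return out


def _carries_ancestral(state: str, t: ClassificationThresholds) -> bool:
    if t.lenient_ancestral:
        return state in ("ancestral_hom", "heterozygous")
    return state == "ancestral_hom"


def _carries_derived(state: str, t: ClassificationThresholds) -> bool:
    if t.lenient_ancestral:
        return state == "derived_hom"
    return state in ("derived_hom", "heterozygous")


def _macaque_states(s: SiteObservation, verdicts, roster) -> Optional[dict[str, str]]:
    """States computed with the macaque base as ancestral proxy; None if the
    macaque base does not match either allele of the site."""
    mac = s.macaque_allele
    if mac not in (s.ref_allele, s.alt_allele):
        return None
    derived = s.alt_allele if mac == s.ref_allele else s.ref_allele
    return compute_states(s, verdicts, mac, derived, roster)


def classify_human_lineage(
    s: SiteObservation,
    verdicts: Mapping[str, FilterVerdict],
    t: ClassificationThresholds,
    roster=None,
) -> ClassifiedSite:
    """Assign the human-lineage category (fixed / HF / extended / none)."""
    roster = list(roster or s.archaic_genotypes)
    neanderthals = [ind for ind in roster if ind in NEANDERTHALS]
    denisovans = [ind for ind in roster if ind not in NEANDERTHALS]
    pol = polarize(s)

    if pol.derived_freq is None:
        # condition (d): macaque stands in for the missing ancestral allele
        states = _macaque_states(s, verdicts, roster)
        if states is not None:
            mac = s.macaque_allele
            derived = s.alt_allele if mac == s.ref_allele else s.ref_allele
            derived_count = s.alt_count if derived == s.alt_allele else s.ref_count
            f = derived_count / s.human_total_count
            if (f > t.hf_human_min
                    and all(st == "ancestral_hom" for st in states.values())):
                return ClassifiedSite(s, "human", "extended", "d", states,
                                      derived, f)
        return ClassifiedSite(s, "none", "none", None, {}, None, None)

    states = compute_states(s, verdicts, s.ancestral_allele, pol.derived_allele,
                            roster)
    f = pol.derived_freq
    n_anc = sum(_carries_ancestral(st, t) for st in states.values())

    # fixed: ancestral allele absent from the human cohort, >=2 archaics ancestral
    ancestral_count = s.human_total_count - pol.derived_count
    if ancestral_count == 0 and n_anc >= 2:
        return ClassifiedSite(s, "human", "fixed", None, states,
                              pol.derived_allele, f)
    if f <= t.hf_human_min:
        return ClassifiedSite(s, "none", "none", None, states,
                              pol.derived_allele, f)
    den_anc = any(_carries_ancestral(states[d], t) for d in denisovans)
    nea_anc = sum(_carries_ancestral(states[n], t) for n in neanderthals)
    if den_anc and nea_anc >= 1:
        return ClassifiedSite(s, "human", "high_frequency", None, states,
                              pol.derived_allele, f)
    present = {ind: st for ind, st in states.items() if st != "missing"}
    # (a) incomplete genotypes, all reliable ones ancestral
    if (len(present) < len(roster) and present
            and all(_carries_ancestral(st, t) for st in present.values())):
        return ClassifiedSite(s, "human", "extended", "a", states,
                              pol.derived_allele, f)
    # (b) third alleles only; no archaic carries the derived allele
    if (present and any(st == "other_allele" for st in present.values())
            and all(st == "other_allele" or _carries_ancestral(st, t)
                    for st in present.values())):
        return ClassifiedSite(s, "human", "extended", "b", states,
                              pol.derived_allele, f)
    # (c) Denisovan ancestral, Neanderthal(s) derived (human-into-Neanderthal flow)
    n_nea_der = sum(_carries_derived(states[n], t) for n in neanderthals)
    c_ok = n_nea_der == 1 if t.extended_c_exactly_one else n_nea_der >= 1
    if den_anc and c_ok:
        return ClassifiedSite(s, "human", "extended", "c", states,
                              pol.derived_allele, f)
    return ClassifiedSite(s, "none", "none", None, states,
                          pol.derived_allele, f)


def classify_archaic_lineage(
    s: SiteObservation,
    verdicts: Mapping[str, FilterVerdict],
    t: ClassificationThresholds,
    roster=None,
) -> ClassifiedSite:
    """Assign the archaic-lineage category (fixed / HF / extended / none)."""
    roster = list(roster or s.archaic_genotypes)
    pol = polarize(s)

    if pol.derived_freq is None:
        # extended: macaque equals the major human allele
        states = _macaque_states(s, verdicts, roster)
        if states is not None:
            mac = s.macaque_allele
            derived = s.alt_allele if mac == s.ref_allele else s.ref_allele
            derived_count = s.alt_count if derived == s.alt_allele else s.ref_count
            f = derived_count / s.human_total_count
            n_der = sum(_carries_derived(st, t) for st in states.values())
            if f < t.archaic_hf_human_derived_max and n_der >= 2:
                return ClassifiedSite(s, "archaic", "extended", "macaque_match",
                                      states, derived, f)
        return ClassifiedSite(s, "none", "none", None, {}, None, None)

    states = compute_states(s, verdicts, s.ancestral_allele, pol.derived_allele,
                            roster)
    f = pol.derived_freq
    n_der = sum(_carries_derived(st, t) for st in states.values())
    # fixed: all three archaics derived, humans ancestral at > 99.999%
    if ((1 - f) > t.archaic_fixed_human_ancestral_min
            and len(roster) >= 3
            and all(_carries_derived(st, t) for st in states.values())):
        return ClassifiedSite(s, "archaic", "fixed", None, states,
                              pol.derived_allele, f)
    if f < t.archaic_hf_human_derived_max and n_der >= 2:
        return ClassifiedSite(s, "archaic", "high_frequency", None, states,
                              pol.derived_allele, f)
    return ClassifiedSite(s, "none", "none", None, states,
                          pol.derived_allele, f)


def classify_site(
    s: SiteObservation,
    verdicts: Mapping[str, FilterVerdict],
    t: ClassificationThresholds,
    roster=None,
) -> ClassifiedSite:
    """Full classification: human lineage first, then archaic, else none.

    The two lineages' frequency conditions are disjoint (f > 0.9 vs
    f < 0.01), so order does not affect which sites are classified, only
    which branch is evaluated first.
    """
    human = classify_human_lineage(s, verdicts, t, roster)
    if human.lineage == "human":
        return human
    archaic = classify_archaic_lineage(s, verdicts, t, roster)
    if archaic.lineage == "archaic":
        return archaic
    return human if human.states else archaic
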