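"""Enrichment statistics: G-tests, length-matched empirical resampling,
hypergeometric and rank-sum category tests with FWER control, and
sweep-region overlap.

The length-matched empirical test is the workhorse: the gene universe is cut
into log-spaced length bins, each of B random gene sets reproduces the
target set's per-bin composition (sampling without replacement within a
bin), and the observed hit statistic is compared with the null draw; the
criterion requires at least a fraction q* (default 90%) of the random sets
to show *strictly* fewer hits.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import RegulatoryFeature, TraitAssociation

logger = logging.getLogger("sncatalog")


@dataclass(frozen=True)
class EnrichmentConfig:
    n_random_sets: int = 1000
    empirical_criterion: float = 0.90
    gtest_p_cutoff: float = 0.1
    min_trait_loci: int = 10
    length_bins: int = 20
    sweep_window_bp: int = 50_000
    fwer_alpha: float = 0.05
    adjusted_p_cutoff: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random_sets < 1:
            raise ValueError("need at least one random set")
        if not 0 < self.empirical_criterion < 1:
            raise ValueError("empirical criterion must lie in (0, 1)")


@dataclass(frozen=True)
class EnrichmentResult:
    test_name: str
    target: str
    statistic: float
    p_value: Optional[float] = None
    empirical_fraction: Optional[float] = None
    n_random_sets: Optional[int] = None
    decision: bool = False
    null_description: str = ""
    details: Mapping[str, float] = field(default_factory=dict)


def substream(seed: int, test_name: str) -> np.random.Generator:
    """Deterministic per-test RNG derived from (seed, test name)."""
    return np.random.default_rng([seed, zlib.crc32(test_name.encode())])


# ---------------------------------------------------------------------------
# G-test
# ---------------------------------------------------------------------------

def g_test(table: Sequence[Sequence[float]], williams: bool = False
           ) -> tuple[float, float]:
    """Log-likelihood-ratio test of independence on a 2x2 count table.

    G = 2 * sum O * ln(O / E) over cells with O > 0, expected counts from
    the independence model, chi-square p-value with 1 df.  No continuity
    correction; the Williams correction is available behind a flag.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("g_test expects a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("row and column sums must be positive")
    expected = np.outer(rows, cols) / n
    if (expected == 0).any():
        raise ValueError("zero expected count")
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    if williams:
        q = 1 + ((n / rows).sum() - 1) * ((n / cols).sum() - 1) / (6 * n)
        g /= q
    return g, float(stats.chi2.sf(g, df=1))


# ---------------------------------------------------------------------------
# length-matched empirical test
# ---------------------------------------------------------------------------

def _length_bins(lengths: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = lengths.min(), lengths.max()
    if lo == hi:
        return np.zeros(len(lengths), dtype=int)
    edges = np.geomspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges, lengths, side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def empirical_length_matched_test(
    target_genes: Sequence[str],
    hit_genes: Sequence[str],
    gene_lengths: Mapping[str, float],
    cfg: EnrichmentConfig,
    rng: Optional[np.random.Generator] = None,
    weights: Optional[Mapping[str, float]] = None,
    test_name: str = "empirical_length_matched",
) -> EnrichmentResult:
    """Empirical gene-set test against B length-matched random sets.

    ``gene_lengths`` defines the universe.  The observed statistic is the
    number of target genes that are hits (or the sum of ``weights`` over
    target genes when per-gene weights, e.g. change counts, are supplied).
    ``empirical_fraction`` is the proportion of random sets with strictly
    fewer hits; the decision requires that fraction to reach the criterion.
    """
    rng = rng if rng is not None else substream(cfg.rng_seed, test_name)
    universe = np.array(sorted(gene_lengths))
    lengths = np.array([gene_lengths[g] for g in universe], dtype=float)
    target = [g for g in dict.fromkeys(target_genes)]
    missing = [g for g in target if g not in gene_lengths]
    if missing:
        raise ValueError(f"target genes outside the universe: {missing[:5]}")
    if weights is None:
        hit_set = set(hit_genes)
        values = np.array([1.0 if g in hit_set else 0.0 for g in universe])
    else:
        values = np.array([float(weights.get(g, 0.0)) for g in universe])
    gene_pos = {g: i for i, g in enumerate(universe)}
    observed = float(values[[gene_pos[g] for g in target]].sum()) if target else 0.0

    n_bins = cfg.length_bins
    while True:
        bins = _length_bins(lengths, n_bins)
        target_bins = np.array([bins[gene_pos[g]] for g in target], dtype=int)
        need = np.bincount(target_bins, minlength=n_bins) if target else \
            np.zeros(n_bins, dtype=int)
        have = np.bincount(bins, minlength=n_bins)
        if (need <= have).all() or n_bins == 1:
            break
        n_bins = max(1, n_bins // 2)
        logger.warning("length bin too small for target set; widening to "
                       "%d bins", n_bins)

    B = cfg.n_random_sets
    null_stats = np.zeros(B)
    for b in range(n_bins):
        k = int(need[b])
        if k == 0:
            continue
        members = np.flatnonzero(bins == b)
        member_vals = values[members]
        m = len(members)
        if k == m:
            null_stats += member_vals.sum()
            continue
        # B simultaneous without-replacement draws of k from m:
        # rank random keys and keep the k smallest per row
        keys = rng.random((B, m))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_stats += member_vals[idx].sum(axis=1)

    fraction = float(np.mean(null_stats < observed))
    return EnrichmentResult(
        test_name=test_name,
        target=f"{len(target)} genes",
        statistic=observed,
        empirical_fraction=fraction,
        n_random_sets=B,
        decision=fraction >= cfg.empirical_criterion,
        null_description=(f"{B} random gene sets length-matched over "
                          f"{n_bins} log-spaced bins"),
    )


# ---------------------------------------------------------------------------
# GWAS-trait enrichment (three-stage screen)
# ---------------------------------------------------------------------------

def gwas_trait_enrichment(
    traits: Sequence[TraitAssociation],
    changes_per_gene: Mapping[str, Mapping[str, int]],
    gene_lengths: Mapping[str, float],
    cfg: EnrichmentConfig,
) -> list[EnrichmentResult]:
    """Per-trait, per-lineage enrichment of HF missense changes.

    ``changes_per_gene`` maps lineage ('human'/'archaic') to per-gene HF
    missense change counts.  A trait is enriched for a lineage iff
    (i) a genome-wide G-test of that lineage's changes in trait genes vs
    trait gene count against genome totals has p below the cutoff,
    (ii) a between-lineage G-test on trait-associated changes has p below
    the cutoff, with the focal lineage over-represented, and
    (iii) the length-matched empirical criterion holds.  Traits with fewer
    associated genes in the universe than ``min_trait_loci`` are skipped.
    """
    by_trait: dict[str, set[str]] = {}
    for a in traits:
        by_trait.setdefault(a.trait_name, set()).add(a.gene_id)

    n_genes_all = len(gene_lengths)
    totals = {lin: sum(counts.values())
              for lin, counts in changes_per_gene.items()}
    results: list[EnrichmentResult] = []
    n_skipped = 0
    for trait in sorted(by_trait):
        genes = sorted(g for g in by_trait[trait] if g in gene_lengths)
        if len(genes) < cfg.min_trait_loci:
            n_skipped += 1
            continue
        in_trait = {lin: sum(changes_per_gene[lin].get(g, 0) for g in genes)
                    for lin in changes_per_gene}
        for lineage in sorted(changes_per_gene):
            other = [l for l in changes_per_gene if l != lineage]
            stage1 = stage2 = stage3 = False
            details: dict[str, float] = {}
            # (i) genome-wide: changes vs genes, trait vs genome
            tbl = [[in_trait[lineage], totals[lineage] - in_trait[lineage]],
                   [len(genes), n_genes_all - len(genes)]]
            try:
                g1, p1 = g_test(tbl)
                details["genomewide_G"], details["genomewide_p"] = g1, p1
                trait_rate = in_trait[lineage] / max(len(genes), 1)
                genome_rate = totals[lineage] / n_genes_all
                stage1 = p1 < cfg.gtest_p_cutoff and trait_rate > genome_rate
            except ValueError:
                pass
            # (ii) between lineages
            if other:
                o = other[0]
                tbl2 = [[in_trait[lineage], totals[lineage] - in_trait[lineage]],
                        [in_trait[o], totals[o] - in_trait[o]]]
                try:
                    g2, p2 = g_test(tbl2)
                    details["lineage_G"], details["lineage_p"] = g2, p2
                    share = in_trait[lineage] / max(totals[lineage], 1)
                    share_o = in_trait[o] / max(totals[o], 1)
                    stage2 = p2 < cfg.gtest_p_cutoff and share > share_o
                except ValueError:
                    pass
            else:
                stage2 = True
            # (iii) empirical length-matched test on change counts
            emp = empirical_length_matched_test(
                genes, [], gene_lengths, cfg,
                weights=changes_per_gene[lineage],
                test_name=f"gwas:{trait}:{lineage}")
            stage3 = emp.decision
            details["empirical_fraction"] = emp.empirical_fraction or 0.0
            details["stage1"], details["stage2"], details["stage3"] = (
                float(stage1), float(stage2), float(stage3))
            results.append(EnrichmentResult(
                test_name="gwas_trait_enrichment",
                target=f"{trait} [{lineage}]",
                statistic=float(in_trait[lineage]),
                p_value=details.get("genomewide_p"),
                empirical_fraction=emp.empirical_fraction,
                n_random_sets=cfg.n_random_sets,
                decision=stage1 and stage2 and stage3,
                null_description="3-stage screen: genome-wide G-test, "
                                 "between-lineage G-test, length-matched "
                                 "empirical test",
                details=details,
            ))
    if n_skipped:
        logger.info("gwas enrichment: skipped %d traits with fewer than %d "
                    "associated loci", n_skipped, cfg.min_trait_loci)
    return results


# ---------------------------------------------------------------------------
# category tests (GO-style) with FWER control
# ---------------------------------------------------------------------------

def category_tests(
    gene_categories: Mapping[str, Sequence[str]],
    foreground: Sequence[str],
    background: Sequence[str] = (),
    mode: str = "hypergeometric",
    scores: Optional[Mapping[str, float]] = None,
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Per-category enrichment with Holm adjustment and permutation FWER.

    hypergeometric mode: ``foreground`` genes are tested against a universe
    of foreground plus ``background`` genes (e.g. genes with synonymous
    changes on the same lineage); upper-tail hypergeometric p per category.

    wilcoxon mode: per-gene ``scores`` (e.g. HF-change ratios) are compared
    in-category vs out-of-category by a one-sided rank-sum test.

    A category is reported iff its Holm-adjusted p is below the cutoff and
    its permutation (max-statistic) FWER estimate is below ``fwer_alpha``.
    """
    if mode not in ("hypergeometric", "wilcoxon"):
        raise ValueError("mode must be 'hypergeometric' or 'wilcoxon'")
    rng = substream(cfg.rng_seed, f"category:{mode}")

    if mode == "hypergeometric":
        fg = set(foreground)
        universe = sorted(fg | set(background))
        uni_arr = np.array(universe)
        fg_mask = np.array([g in fg for g in universe])
        cats = {name: np.array([g in set(members) for g in universe])
                for name, members in gene_categories.items()
                if any(g in set(members) for g in universe)}
        skipped = set(gene_categories) - set(cats)

        def pvals_for(mask: np.ndarray) -> dict[str, float]:
            n_fg = int(mask.sum())
            out = {}
            for name, cat_mask in cats.items():
                K = int(cat_mask.sum())
                k = int((cat_mask & mask).sum())
                out[name] = float(stats.hypergeom.sf(k - 1, len(universe), K, n_fg))
            return out

        observed_p = pvals_for(fg_mask)
        statistic = {name: float((cats[name] & fg_mask).sum()) for name in cats}
        n_fg = int(fg_mask.sum())

        def permuted_min_p() -> float:
            idx = rng.choice(len(universe), size=n_fg, replace=False)
            mask = np.zeros(len(universe), dtype=bool)
            mask[idx] = True
            return min(pvals_for(mask).values())
    else:
        if scores is None:
            raise ValueError("wilcoxon mode requires per-gene scores")
        universe = sorted(scores)
        vals = np.array([scores[g] for g in universe], dtype=float)
        cats = {name: np.array([g in set(members) for g in universe])
                for name, members in gene_categories.items()
                if 0 < sum(g in set(members) for g in universe) < len(universe)}
        skipped = set(gene_categories) - set(cats)

        def pvals_for(values: np.ndarray) -> dict[str, float]:
            out = {}
            for name, cat_mask in cats.items():
                res = stats.mannwhitneyu(values[cat_mask], values[~cat_mask],
                                         alternative="greater")
                out[name] = float(res.pvalue)
            return out

        observed_p = pvals_for(vals)
        statistic = {name: float(np.median(vals[cats[name]])) for name in cats}

        def permuted_min_p() -> float:
            return min(pvals_for(rng.permutation(vals)).values())

    if skipped:
        logger.info("category tests: skipped %d categories with no members "
                    "in the universe", len(skipped))
    if not cats:
        return []

    names = sorted(cats)
    raw = np.array([observed_p[n] for n in names])
    holm = multipletests(raw, method="holm")[1]
    perm_min = np.array([permuted_min_p() for _ in range(cfg.n_random_sets)])
    results = []
    for i, name in enumerate(names):
        fwer = float(np.mean(perm_min <= raw[i]))
        results.append(EnrichmentResult(
            test_name=f"category_{mode}",
            target=name,
            statistic=statistic[name],
            p_value=float(raw[i]),
            n_random_sets=cfg.n_random_sets,
            decision=bool(holm[i] < cfg.adjusted_p_cutoff
                          and fwer < cfg.fwer_alpha),
            null_description="Holm adjustment + permutation max-statistic FWER",
            details={"holm_p": float(holm[i]), "fwer": fwer},
        ))
    return results


# ---------------------------------------------------------------------------
# sweep overlap
# ---------------------------------------------------------------------------

def sweep_overlap(site_positions: Sequence[tuple[str, int]],
                  regions: Sequence[RegulatoryFeature],
                  window: int = 50_000) -> list[tuple[str, int]]:
    """Sites within ``window`` bp of any sweep region (distance 0 inside)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(
            max(1, r.start - window), r.end + window + 1)
    return [(chrom, pos) for chrom, pos in site_positions
            if chrom in trees and trees[chrom][pos]]
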