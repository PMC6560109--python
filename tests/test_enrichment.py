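"""Enrichment statistics: exact oracles for the G-test and hypergeometric
test, determinism and extreme cases of the length-matched empirical test,
Holm/FWER behaviour, and the sweep-window overlap."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.stats import chi2_contingency

from sncatalog.enrichment import (EnrichmentConfig, category_tests,
                                  empirical_length_matched_test, g_test,
                                  gwas_trait_enrichment, sweep_overlap,
                                  substream)
from sncatalog.model import RegulatoryFeature, TraitAssociation


class TestGTest:
    def test_worked_example(self):
        g, p = g_test([[10, 20], [30, 40]])
        # direct evaluation of 2*sum O ln(O/E)
        assert g == pytest.approx(0.8042, abs=5e-4)
        assert p == pytest.approx(sps.chi2.sf(g, 1))

    def test_proportional_rows_give_zero(self):
        g, p = g_test([[10, 20], [30, 60]])
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_large_positive(self):
        g, _ = g_test([[0, 10], [10, 0]])
        assert g > 20

    def test_matches_direct_formula_on_random_tables(self, rng):
        for _ in range(1000):
            obs = rng.integers(1, 200, size=(2, 2)).astype(float)
            g, _ = g_test(obs)
            n = obs.sum()
            e = np.outer(obs.sum(1), obs.sum(0)) / n
            oracle = 2 * np.sum(obs * np.log(obs / e))
            assert g == pytest.approx(oracle, rel=1e-9)

    def test_matches_scipy_log_likelihood(self, rng):
        for _ in range(200):
            obs = rng.integers(1, 100, size=(2, 2))
            g, p = g_test(obs)
            res = chi2_contingency(obs, correction=False,
                                   lambda_="log-likelihood")
            assert g == pytest.approx(res.statistic, rel=1e-12)
            assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            g_test([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            g_test([[1, 2, 3], [4, 5, 6]])  # not 2x2


def exhaustive_hypergeom_upper_p(N, K, n, k_obs):
    """Exact enumeration over all C(N, n) draws."""
    universe = range(N)
    hits = set(range(K))
    total = more = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(hits.intersection(draw)) >= k_obs:
            more += 1
    return more / total


class TestHypergeometric:
    def test_worked_example_exact_fraction(self):
        """N=20, K=5, n=6, k=4: upper-tail p = 540/38760."""
        p = float(sps.hypergeom.sf(3, 20, 5, 6))
        assert p == pytest.approx(540 / 38760, rel=1e-12)
        assert exhaustive_hypergeom_upper_p(20, 5, 6, 4) == \
            pytest.approx(540 / 38760, rel=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [
        (12, 4, 5, 2), (15, 6, 4, 3), (20, 5, 6, 4), (25, 10, 5, 4),
        (30, 8, 4, 2), (18, 9, 6, 5),
    ])
    def test_category_test_matches_enumeration(self, N, K, n, k):
        """The hypergeometric mode reproduces exhaustive enumeration for
        small universes."""
        universe = [f"g{i}" for i in range(N)]
        category = {"cat": universe[:K]}
        foreground = universe[:k] + universe[K:K + (n - k)]
        background = [g for g in universe if g not in set(foreground)]
        (res,) = category_tests(category, foreground, background,
                                mode="hypergeometric",
                                cfg=EnrichmentConfig(n_random_sets=50,
                                                     rng_seed=1))
        assert res.p_value == pytest.approx(
            exhaustive_hypergeom_upper_p(N, K, n, k), rel=1e-9)


class TestEmpiricalLengthMatched:
    def _universe(self, rng, n=500):
        return {f"g{i}": float(l)
                for i, l in enumerate(np.exp(rng.normal(9, 0.7, n)))}

    def test_empty_hit_set(self, rng):
        lengths = self._universe(rng)
        genes = list(lengths)
        res = empirical_length_matched_test(genes[:20], [], lengths,
                                            EnrichmentConfig(n_random_sets=100))
        assert (res.statistic, res.empirical_fraction, res.decision) == \
            (0.0, 0.0, False)

    def test_target_equals_rare_hits(self, rng):
        lengths = self._universe(rng)
        genes = sorted(lengths)
        target = genes[::25]  # 20 genes spread over the length range
        res = empirical_length_matched_test(target, target, lengths,
                                            EnrichmentConfig(n_random_sets=200))
        assert res.statistic == len(target)
        assert res.empirical_fraction > 0.95 and res.decision

    def test_seed_determinism_and_stability(self, rng):
        lengths = self._universe(rng)
        genes = sorted(lengths)
        hits = genes[::7]
        cfg = EnrichmentConfig(n_random_sets=300, rng_seed=5)
        r1 = empirical_length_matched_test(genes[:40], hits, lengths, cfg)
        r2 = empirical_length_matched_test(genes[:40], hits, lengths, cfg)
        assert r1.empirical_fraction == r2.empirical_fraction
        other = empirical_length_matched_test(
            genes[:40], hits, lengths,
            EnrichmentConfig(n_random_sets=300, rng_seed=6))
        se = math.sqrt(0.25 / 300)
        assert abs(r1.empirical_fraction - other.empirical_fraction) < 6 * se

    def test_target_outside_universe_rejected(self, rng):
        lengths = self._universe(rng)
        with pytest.raises(ValueError):
            empirical_length_matched_test(["nope"], [], lengths,
                                          EnrichmentConfig(n_random_sets=10))

    def test_weights_sum_statistic(self, rng):
        lengths = self._universe(rng)
        genes = sorted(lengths)
        weights = {g: 2.0 for g in genes[:10]}
        res = empirical_length_matched_test(
            genes[:10], [], lengths, EnrichmentConfig(n_random_sets=50),
            weights=weights)
        assert res.statistic == 20.0


class TestGwasScreen:
    def _setup(self, swap=False):
        rng = np.random.default_rng(3)
        lengths = {f"g{i}": float(l)
                   for i, l in enumerate(np.exp(rng.normal(9, 0.5, 300)))}
        human = {g: int(rng.poisson(3)) for g in lengths}
        archaic = {g: int(rng.poisson(3)) for g in lengths}
        trait_genes = sorted(lengths)[:15]
        for g in trait_genes:
            human[g] = int(human[g] * 5 + 10)  # planted human excess
        traits = [TraitAssociation("planted", g) for g in trait_genes]
        traits += [TraitAssociation("tiny", g) for g in sorted(lengths)[20:29]]
        changes = {"human": human, "archaic": archaic}
        if swap:
            changes = {"human": archaic, "archaic": human}
        return traits, changes, lengths

    def test_planted_trait_enriched_for_human(self):
        traits, changes, lengths = self._setup()
        results = gwas_trait_enrichment(
            traits, changes, lengths,
            EnrichmentConfig(n_random_sets=200, rng_seed=9))
        by_target = {r.target: r for r in results}
        assert by_target["planted [human]"].decision
        assert not by_target["planted [archaic]"].decision
        # trait with 9 loci skipped entirely
        assert not any(r.target.startswith("tiny") for r in results)

    def test_swapping_lineages_flips_the_enrichment(self):
        traits, changes, lengths = self._setup(swap=True)
        results = gwas_trait_enrichment(
            traits, changes, lengths,
            EnrichmentConfig(n_random_sets=200, rng_seed=9))
        by_target = {r.target: r for r in results}
        assert by_target["planted [archaic]"].decision
        assert not by_target["planted [human]"].decision


class TestCategoryTests:
    def test_holm_never_decreases_p(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(60)]
        cats = {f"c{j}": list(rng.choice(universe, 12, replace=False))
                for j in range(5)}
        fg = list(rng.choice(universe, 20, replace=False))
        bg = [g for g in universe if g not in set(fg)]
        results = category_tests(cats, fg, bg, mode="hypergeometric",
                                 cfg=EnrichmentConfig(n_random_sets=100,
                                                      rng_seed=2))
        for r in results:
            assert r.details["holm_p"] >= r.p_value

    def test_wilcoxon_mode_detects_shifted_category(self):
        rng = np.random.default_rng(5)
        scores = {f"g{i}": float(rng.normal()) for i in range(200)}
        shifted = [f"g{i}" for i in range(20)]
        for g in shifted:
            scores[g] += 3.0
        results = category_tests({"up": shifted, "null": [f"g{i}" for i in
                                                          range(50, 70)]},
                                 [], scores=scores, mode="wilcoxon",
                                 cfg=EnrichmentConfig(n_random_sets=200,
                                                      rng_seed=3))
        by = {r.target: r for r in results}
        assert by["up"].decision and by["up"].details["holm_p"] < 1e-6
        assert not by["null"].decision

    def test_wilcoxon_null_p_is_uniformish(self):
        """Identical score distributions in and out of category: median p
        over replicates sits near 0.5."""
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(100 + rep)
            scores = {f"g{i}": float(rng.normal()) for i in range(80)}
            (res,) = category_tests(
                {"c": [f"g{i}" for i in range(20)]}, [], scores=scores,
                mode="wilcoxon", cfg=EnrichmentConfig(n_random_sets=1,
                                                      rng_seed=rep))
            ps.append(res.p_value)
        assert 0.4 <= float(np.median(ps)) <= 0.6

    def test_permuted_foreground_rarely_passes(self):
        """Null calibration: with a random foreground, the number of
        decisions across replicates stays near the nominal level."""
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(100)]
        cats = {f"c{j}": list(rng.choice(universe, 15, replace=False))
                for j in range(4)}
        n_hits = 0
        n_rep = 60
        for rep in range(n_rep):
            fg = list(rng.choice(universe, 30, replace=False))
            bg = [g for g in universe if g not in set(fg)]
            results = category_tests(cats, fg, bg, mode="hypergeometric",
                                     cfg=EnrichmentConfig(n_random_sets=60,
                                                          rng_seed=rep))
            n_hits += any(r.decision for r in results)
        assert n_hits <= 8  # family-level false positives stay rare


class TestSweepOverlap:
    REGIONS = [RegulatoryFeature("1", 1_000_000, 1_010_000, "sweep_region")]

    @pytest.mark.parametrize("pos,included", [
        (1_005_000, True),    # inside
        (1_000_000 - 49_999, True),
        (1_000_000 - 50_000, True),   # exactly at the window
        (1_000_000 - 50_001, False),
        (1_010_000 + 50_000, True),
        (1_010_000 + 50_001, False),
    ])
    def test_window_boundaries(self, pos, included):
        got = sweep_overlap([("1", pos)], self.REGIONS, 50_000)
        assert (("1", pos) in got) == included

    def test_empty_region_list(self):
        assert sweep_overlap([("1", 5)], [], 50_000) == []


def test_substreams_are_deterministic_and_distinct():
    a = substream(1, "x").random(3)
    b = substream(1, "x").random(3)
    c = substream(1, "y").random(3)
    assert (a == b).all() and not (a == c).all()
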