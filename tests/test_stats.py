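"""Divergence, chromosome-distribution and enrichment statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (hypergeom_tails_by_enumeration, hypergeom_upper_tail_comb,
                     p_distance_sites)
from satdisperse import (category_enrichment, chromosome_distribution_test,
                         p_distance_matrix)
from satdisperse.synthetic import make_consensus_pair, mutate
from conftest import random_seq


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = p_distance_matrix({"s1": "ACGT" * 25, "s2": "ACGT" * 25})
        assert dm.values[0, 1] == 0.0

    def test_one_difference_in_hundred_sites(self):
        a = "ACGT" * 25
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        dm = p_distance_matrix([("a", a), ("b", b)])
        assert dm.values[0, 1] == pytest.approx(0.01)

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        seqs = {f"s{i}": random_seq(rng, 120) for i in range(4)}
        dm = p_distance_matrix(seqs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_equals_site_count_oracle_on_generator_alignment(self, rng):
        """Substitution-only mutants of a common monomer stay co-linear, so
        the p-distance on the generator's own alignment must equal the
        direct per-site count exactly."""
        a, _ = make_consensus_pair(17)
        mutants = [(f"m{i}", mutate(rng, a.sequence, 0.06)) for i in range(8)]
        dm = p_distance_matrix(mutants, alignment="precomputed")
        for i in range(8):
            for j in range(i + 1, 8):
                direct = p_distance_sites(mutants[i][1], mutants[j][1])
                assert dm.values[i, j] == pytest.approx(direct, abs=1e-12)

    def test_realignment_stays_close_to_true_alignment(self, rng):
        """Score-optimal realignment may swap a few substitutions for gap
        pairs; the deflation against the true alignment stays small."""
        a, _ = make_consensus_pair(17)
        mutants = [(f"m{i}", mutate(rng, a.sequence, 0.06)) for i in range(5)]
        realigned = p_distance_matrix(mutants, alignment="global")
        true = p_distance_matrix(mutants, alignment="precomputed")
        assert np.all(realigned.values <= true.values + 1e-12)
        assert np.max(true.values - realigned.values) < 0.02

    def test_mean_pairwise_of_six_percent_mutants_in_expected_band(self, rng):
        a, _ = make_consensus_pair(23)
        mutants = [(f"m{i}", mutate(rng, a.sequence, 0.06)) for i in range(30)]
        dm = p_distance_matrix(mutants)
        assert 0.10 <= dm.mean_pairwise <= 0.13

    def test_zero_length_sequences_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            dm = p_distance_matrix([("a", "ACGTACGT"), ("b", ""),
                                    ("c", "ACGTACGA")])
        assert dm.labels == ["a", "c"]


class TestChromosomeTest:
    def test_uniform_counts_under_equal_weights_not_significant(self):
        counts = {f"chr{i}": 5 for i in range(10)}
        weights = {f"chr{i}": 0.1 for i in range(10)}
        results = chromosome_distribution_test(counts, weights)
        assert not any(r.significant for r in results)
        assert all(r.p_bonferroni >= r.p_two_tailed for r in results)

    def test_extreme_count_matches_integer_arithmetic_enumeration(self):
        """n=20 on two equally weighted chromosomes, split (20, 0): the
        doubled smaller tail must equal the exact hypergeometric sum."""
        counts = {"c1": 20, "c2": 0}
        weights = {"c1": 0.5, "c2": 0.5}
        results = chromosome_distribution_test(counts, weights, pool_size=10 ** 6)
        M, K, n = 10 ** 6, 500_000, 20

        def pmf(k):
            return (math.comb(K, k) * math.comb(M - K, n - k)
                    / math.comb(M, n))

        upper = sum(pmf(k) for k in range(20, 21))
        lower = sum(pmf(k) for k in range(0, 21))
        expected_c1 = min(1.0, 2 * min(lower, upper))
        got = {r.chrom: r for r in results}
        assert got["c1"].p_two_tailed == pytest.approx(expected_c1, rel=1e-9)
        assert got["c1"].significant and got["c2"].significant

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            chromosome_distribution_test({"a": 1, "b": 1},
                                         {"a": 0.5, "b": 0.6})

    def test_chromosome_sets_must_agree(self):
        with pytest.raises(ValueError, match="differ"):
            chromosome_distribution_test({"a": 1}, {"b": 1.0})


class TestEnrichment:
    BACKGROUND = [f"g{i}" for i in range(10)]

    def _annotation(self, k_members):
        return {g: ("hit" if i < k_members else "other")
                for i, g in enumerate(self.BACKGROUND)}

    def test_small_case_equals_subset_enumeration(self):
        """N=10, K=5, n=4, k=4: p = C(5,4) C(5,0) / C(10,4), checked by
        literally enumerating every 4-subset."""
        annotation = self._annotation(5)
        gene_set = self.BACKGROUND[:4]
        results = category_enrichment(gene_set, annotation, self.BACKGROUND)
        hit = next(r for r in results if r.category == "hit")
        _, ge = hypergeom_tails_by_enumeration(4, 10, 5, 4)
        assert hit.p_raw == pytest.approx(ge, rel=1e-12)
        assert hit.p_raw == pytest.approx(
            math.comb(5, 4) * math.comb(5, 0) / math.comb(10, 4), rel=1e-12)

    def test_k_zero_has_p_one(self):
        annotation = self._annotation(5)
        gene_set = self.BACKGROUND[5:9]  # no "hit" members
        results = category_enrichment(gene_set, annotation, self.BACKGROUND)
        hit = next(r for r in results if r.category == "hit")
        assert hit.p_raw == pytest.approx(1.0)

    def test_p_monotone_decreasing_in_k(self):
        annotation = self._annotation(5)
        previous = 1.1
        for k in range(0, 5):
            gene_set = self.BACKGROUND[:k] + self.BACKGROUND[5:9 - k]
            results = category_enrichment(gene_set, annotation, self.BACKGROUND)
            hit = next(r for r in results if r.category == "hit")
            assert hit.p_raw < previous or k == 0
            previous = hit.p_raw

    def test_bonferroni_at_least_raw_and_capped(self):
        annotation = {g: ["hit", "other", "third"] for g in self.BACKGROUND}
        results = category_enrichment(self.BACKGROUND[:4], annotation,
                                      self.BACKGROUND)
        for r in results:
            assert r.p_raw <= r.p_corrected <= 1.0

    def test_bh_correction_available(self):
        annotation = self._annotation(5)
        results = category_enrichment(self.BACKGROUND[:4], annotation,
                                      self.BACKGROUND, correction="bh")
        assert all(0 <= r.p_corrected <= 1 for r in results)

    def test_gene_set_must_be_subset_of_background(self):
        with pytest.raises(ValueError, match="subset"):
            category_enrichment(["zz"], self._annotation(5), self.BACKGROUND)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_upper_tail_matches_integer_arithmetic_for_small_n(self, data):
        N = data.draw(st.integers(2, 25))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n)))
        from scipy.stats import hypergeom
        scipy_tail = float(hypergeom.sf(k - 1, N, K, n))
        assert scipy_tail == pytest.approx(
            hypergeom_upper_tail_comb(k, N, K, n), rel=1e-9)

    def test_literal_enumeration_agrees_for_tiny_universes(self):
        for (N, K, n, k) in [(8, 3, 4, 2), (10, 5, 4, 4), (12, 6, 5, 1),
                             (9, 2, 6, 0), (11, 7, 3, 3)]:
            le, ge = hypergeom_tails_by_enumeration(k, N, K, n)
            assert ge == pytest.approx(hypergeom_upper_tail_comb(k, N, K, n),
                                       rel=1e-12)
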