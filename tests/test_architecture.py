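"""Dot-matrix, tandem segmentation, TIR/TSD detection, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_dot_matches, p_distance_sites, rc
from satdisperse import (assign_subfamily, classify, detect_tirs, detect_tsd,
                         dot_matrix, flank_at_content, revcomp,
                         segment_tandem)
from satdisperse.architecture import SubunitAnnotation, TransposonFeatures
from satdisperse.synthetic import mutate
from conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestDotMatrix:
    def test_self_comparison_has_full_main_diagonal(self, rng):
        seq = random_seq(rng, 80)
        dm = dot_matrix(seq, seq, window=9, mismatch_limit=0)
        for i in range(80 - 9 + 1):
            assert (i, i) in dm.forward_matches

    def test_perfect_tandem_shows_periodic_off_diagonals(self):
        unit = "ACGTTGCAGG"
        seq = unit * 5
        dm = dot_matrix(seq, seq, window=9, mismatch_limit=0)
        p = len(unit)
        for k in range(1, 5):
            offset_hits = [(i, j) for (i, j) in dm.forward_matches
                           if j - i == k * p]
            assert len(offset_hits) == len(seq) - k * p - 9 + 1

    def test_forward_matches_equal_brute_force_on_reverse_complement(self, rng):
        seq = random_seq(rng, 200)
        dm = dot_matrix(seq, revcomp(seq), window=9, mismatch_limit=0)
        assert dm.forward_matches == naive_dot_matches(seq, revcomp(seq), 9, 0)

    def test_reverse_channel_equals_brute_force(self, rng):
        a, b = random_seq(rng, 120), random_seq(rng, 90)
        dm = dot_matrix(a, b, window=11, mismatch_limit=1)
        assert dm.reverse_matches == naive_dot_matches(a, b, 11, 1, reverse=True)

    def test_sequences_shorter_than_window_give_empty_matrix(self):
        dm = dot_matrix("ACGT", "ACGTACGTA", window=9)
        assert not dm.forward_matches and not dm.reverse_matches

    def test_non_acgt_never_matches(self):
        dm = dot_matrix("N" * 20, "N" * 20, window=9)
        assert not dm.forward_matches

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=dna, b=dna, window=st.integers(4, 12),
           limit=st.integers(0, 2))
    def test_matches_equal_naive_oracle(self, a, b, window, limit):
        if limit >= window:
            limit = window - 1
        dm = dot_matrix(a, b, window=window, mismatch_limit=limit)
        assert dm.forward_matches == naive_dot_matches(a, b, window, limit)
        assert dm.reverse_matches == naive_dot_matches(a, b, window, limit,
                                                       reverse=True)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            dot_matrix("ACGTACGT", "ACGTACGT", window=3)
        with pytest.raises(ValueError):
            dot_matrix("ACGTACGT", "ACGTACGT", window=9, mismatch_limit=9)


class TestSegmentTandem:
    def test_four_exact_monomers_count_four_copies(self, consensus_pair):
        a, _ = consensus_pair
        subunits, copies = segment_tandem(a.sequence * 4, consensus_pair)
        assert copies == 4.0
        assert len(subunits) == 4
        assert all(s.subfamily == "a" and s.orientation == "+"
                   for s in subunits)

    def test_exact_dimer_of_subfamily_b_counts_two(self, consensus_pair):
        _, b = consensus_pair
        subunits, copies = segment_tandem(b.sequence * 2, consensus_pair)
        assert copies == 2.0
        assert all(s.subfamily == "b" for s in subunits)

    def test_203bp_partial_monomer_rounds_to_0_6(self, consensus_pair):
        a, _ = consensus_pair
        _, copies = segment_tandem(a.sequence[:203], consensus_pair)
        assert copies == 0.6  # 203/362 = 0.56, half-up to one decimal

    def test_diverged_tandem_copies_survive_mutation(self, consensus_pair, rng):
        _, b = consensus_pair
        seq = mutate(rng, b.sequence * 3, 0.06)
        _, copies = segment_tandem(seq, consensus_pair)
        assert copies == pytest.approx(3.0, abs=0.1)

    def test_appending_a_monomer_adds_exactly_one_copy(self, consensus_pair):
        a, _ = consensus_pair
        for n in (1, 2, 3):
            _, before = segment_tandem(a.sequence * n, consensus_pair)
            _, after = segment_tandem(a.sequence * (n + 1), consensus_pair)
            assert after - before == pytest.approx(1.0, abs=1e-9)

    def test_random_sequence_has_no_subunits(self, rng):
        a = random_seq(rng, 500)
        from satdisperse import make_consensus_pair
        subunits, copies = segment_tandem(a, make_consensus_pair(5))
        assert subunits == [] and copies == 0.0


class TestAssignSubfamily:
    def test_exact_copies_assigned_to_their_own_subfamily(self, consensus_pair):
        a, b = consensus_pair
        assert assign_subfamily(a.sequence, a, b) == "a"
        assert assign_subfamily(b.sequence, a, b) == "b"

    def test_chimera_dominated_by_a_divergent_region_goes_to_a(self,
                                                               consensus_pair):
        a, b = consensus_pair
        s, e = a.divergent_region
        chimera = a.sequence[s:e] + b.sequence[255:322]  # 100 bp a + 67 bp b
        # oracle check: the chimera is closer to a than to b site-by-site
        frag_a = a.sequence[s:e] + a.sequence[s + 100:s + 167]
        assert assign_subfamily(chimera, a, b) == "a"

    def test_diverged_monomer_keeps_its_subfamily(self, consensus_pair, rng):
        a, b = consensus_pair
        for _ in range(5):
            assert assign_subfamily(mutate(rng, a.sequence, 0.08), a, b) == "a"
            assert assign_subfamily(mutate(rng, b.sequence, 0.08), a, b) == "b"


class TestDetectTirs:
    def test_exact_269bp_arms_detected_in_full(self, rng):
        arm = random_seq(rng, 269)
        elem = arm + random_seq(rng, 306) + revcomp(arm)
        feats = detect_tirs(elem)
        assert feats is not None
        assert feats.arm_length == 269
        assert feats.arm_identity == 1.0
        assert feats.tir_left == (0, 269)
        assert feats.tir_right == (len(elem) - 269, len(elem))

    def test_random_sequences_yield_none(self):
        for seed in range(20):
            local = np.random.default_rng(seed)
            assert detect_tirs(random_seq(local, 800)) is None

    def test_mutated_arms_report_identity_near_planted(self, rng):
        arm = random_seq(rng, 260)
        spacer = random_seq(rng, 300)
        for seed in range(3):
            local = np.random.default_rng(seed)
            left = mutate(local, arm, 0.05)
            right = mutate(local, arm, 0.05)
            planted_identity = p_distance_sites(left, right)
            elem = left + spacer + revcomp(right)
            feats = detect_tirs(elem)
            assert feats is not None
            assert feats.arm_identity == pytest.approx(1 - planted_identity,
                                                       abs=0.03)

    def test_arms_far_from_ends_rejected(self, rng):
        arm = random_seq(rng, 100)
        elem = random_seq(rng, 120) + arm + random_seq(rng, 200) + \
            revcomp(arm) + random_seq(rng, 120)
        assert detect_tirs(elem) is None


class TestDetectTsd:
    def test_act_duplication_found(self, rng):
        chrom = random_seq(rng, 200) + "ACT" + random_seq(rng, 300) + "ACT" + \
            random_seq(rng, 200)
        tsd = detect_tsd(chrom, (203, 503))
        assert tsd is not None and tsd.kmer == "ACT" and tsd.shift == 0

    def test_different_flanks_yield_none(self, rng):
        chrom = random_seq(rng, 100) + "GGG" + "C" * 300 + "TTT" + \
            random_seq(rng, 100)
        assert detect_tsd(chrom, (103, 403)) is None

    def test_duplication_at_plus_one_shift_reported(self):
        # "CAT" duplicates only when both boundaries shift by +1 (the left
        # probe then ends on the element's first base); probes at shifts 0
        # and -1 are engineered to differ
        chrom = "GGGGGTCA" + "T" + "A" * 49 + "GCAT" + "GGGG"
        tsd = detect_tsd(chrom, (8, 58))
        assert tsd is not None
        assert tsd.kmer == "CAT" and tsd.shift == 1

    def test_strand_symmetric(self, rng):
        chrom = random_seq(rng, 150) + "ACT" + random_seq(rng, 250) + "ACT" + \
            random_seq(rng, 150)
        iv = (153, 403)
        fwd = detect_tsd(chrom, iv)
        n = len(chrom)
        rev = detect_tsd(revcomp(chrom), (n - iv[1], n - iv[0]))
        assert fwd is not None and rev is not None
        assert rev.kmer == revcomp(fwd.kmer)

    def test_contig_edge_returns_none(self):
        assert detect_tsd("ACTGGGACT", (3, 6)) is None


class TestClassify:
    def _subunit(self, start, end, orientation="+"):
        return SubunitAnnotation(start, end, "a", (end - start) / 362,
                                 orientation)

    def test_inverted_subunits_with_spacer_is_transposon(self):
        subunits = [self._subunit(0, 362), self._subunit(668, 789, "-")]
        assert classify(subunits, None) == "transposon"

    def test_pure_trimer_is_satellite(self):
        subunits = [self._subunit(i * 362, (i + 1) * 362) for i in range(3)]
        assert classify(subunits, None) == "satellite"

    def test_tir_pair_overlapping_subunit_is_transposon(self):
        feats = TransposonFeatures(tir_left=(0, 269), tir_right=(700, 969),
                                   arm_length=269, arm_identity=0.9)
        subunits = [self._subunit(148, 510)]
        assert classify(subunits, feats) == "transposon"

    def test_inverted_subunits_without_spacer_is_satellite(self):
        # immediately adjacent inverted content, no unique spacer
        subunits = [self._subunit(0, 362), self._subunit(370, 491, "-")]
        assert classify(subunits, None) == "satellite"


class TestFlankAt:
    def test_pure_at_and_pure_gc_flanks(self):
        chrom = "A" * 100 + "CCCGGG" + "G" * 50 + "C" * 50
        at5, at3 = flank_at_content(chrom, (100, 106))
        assert at5 == 1.0 and at3 == 0.0

    def test_matches_direct_count_on_random_sequence(self, rng):
        chrom = random_seq(rng, 600)
        at5, at3 = flank_at_content(chrom, (250, 350))
        left = chrom[150:250]
        right = chrom[350:450]
        assert at5 == (left.count("A") + left.count("T")) / 100
        assert at3 == (right.count("A") + right.count("T")) / 100

    def test_truncated_flank_at_contig_start(self):
        chrom = "AT" + "G" * 100
        at5, at3 = flank_at_content(chrom, (2, 52))
        assert at5 == 1.0  # only 2 bases available
        assert at3 == 0.0

    def test_zero_available_flank_is_none(self):
        chrom = "G" * 50
        at5, at3 = flank_at_content(chrom, (0, 50))
        assert at5 is None and at3 is None
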