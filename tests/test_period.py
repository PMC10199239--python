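import numpy as np
import pytest

import oracles
from conftest import random_seq
from satkit import (
    consensus_from_hits,
    estimate_period,
    kmer_distance_histogram,
    map_pattern,
    maybe_split_period,
    sample_candidates,
    scan_pattern,
    select_best_candidate,
    split_unmapped,
)
from satkit.period import NoMappableMonomer, PatternHit
from satkit.regions import RepetitiveRegion
from satkit.synth import generate_array, generate_monomer


class TestKmerDistanceHistogram:
    def test_period3_string(self):
        hist = kmer_distance_histogram("ACT" * 50, k=10)
        assert max(hist, key=hist.get) == 3

    def test_diverged_array_mode_at_monomer_length(self):
        monomer = generate_monomer(178, seed=3)
        array, _ = generate_array(monomer, 20, sub_rate=0.01, seed=3)
        hist = kmer_distance_histogram(array, k=10, max_monomer=1000)
        assert max(hist, key=hist.get) == 178

    def test_short_region_empty(self):
        assert kmer_distance_histogram("ACGTACGT", k=10) == {}

    def test_distances_capped_at_max_monomer(self):
        monomer = generate_monomer(60, seed=4)
        hist = kmer_distance_histogram(monomer * 5, k=10, max_monomer=59)
        assert all(d <= 59 for d in hist)


class TestEstimatePeriod:
    def test_below_minimum_is_no_repeat(self):
        assert estimate_period({3: 100}, min_monomer=4) is None

    def test_argmax(self):
        est = estimate_period({178: 900, 356: 400})
        assert est.N == 178 and est.mode_count == 900

    def test_tie_breaks_to_smallest(self):
        assert estimate_period({100: 50, 200: 50}).N == 100


class TestMaybeSplitPeriod:
    def test_default_threshold_is_identity(self):
        hist = {680: 1000, 170: 900, 340: 950}
        assert maybe_split_period(hist, 680, threshold_pct=100.0) == 680

    def test_alternating_variant_dimer_splits(self):
        """Array of a 100 bp monomer in two alternating variants: k-mer mode
        sits at 200 but enough identical k-mers recur at 100 to split."""
        rng = np.random.default_rng(8)
        monomer = generate_monomer(100, seed=8)
        variant = list(monomer)
        for pos in rng.choice(100, size=10, replace=False):
            variant[pos] = str(rng.choice([b for b in "ACGT" if b != variant[pos]]))
        array = (monomer + "".join(variant)) * 15
        hist = kmer_distance_histogram(array, k=10, max_monomer=1000)
        assert max(hist, key=hist.get) == 200
        assert maybe_split_period(hist, 200, threshold_pct=10.0) == 100
        # hand-checked against the histogram: mass near 100 exceeds 10% of mode
        s_100 = sum(c for d, c in hist.items() if abs(d - 100) <= 2)
        assert s_100 >= 0.10 * hist[200]

    def test_composite_divisor_requires_proper_divisors(self):
        # mass at N/4 but none at N/2: d=4 must not fire
        hist = {400: 1000, 100: 800}
        assert maybe_split_period(hist, 400, threshold_pct=50.0) == 400
        # adding mass at N/2 unlocks d=4
        hist = {400: 1000, 200: 800, 100: 800}
        assert maybe_split_period(hist, 400, threshold_pct=50.0) == 100

    def test_result_divides_N(self, rng):
        for _ in range(20):
            N = int(rng.integers(40, 900))
            hist = {int(d): int(c) for d, c in
                    zip(rng.integers(4, 1000, 12), rng.integers(1, 500, 12))}
            hist[N] = 1000
            out = maybe_split_period(hist, N, threshold_pct=30.0)
            if out != N:
                assert any(out == round(N / d) for d in range(2, 13))


class TestSampleCandidates:
    def test_region_of_length_N(self, rng):
        cands = sample_candidates("ACGTACGT", 8, 3, rng)
        assert cands == ["ACGTACGT"] * 3

    def test_deterministic_per_seed(self):
        seq = generate_monomer(500, seed=1) * 3
        a = sample_candidates(seq, 100, 6, np.random.default_rng(42))
        b = sample_candidates(seq, 100, 6, np.random.default_rng(42))
        assert a == b

    def test_candidates_are_rotations_of_monomer(self, rng):
        monomer = generate_monomer(50, seed=2)
        array = monomer * 20
        for cand in sample_candidates(array, 50, 10, rng):
            assert cand in monomer + monomer

    def test_region_shorter_than_period(self, rng):
        with pytest.raises(ValueError, match="shorter than period"):
            sample_candidates("ACGT", 10, 3, rng)


class TestMapPattern:
    def test_pattern_equals_region(self):
        hits = map_pattern("ACGTACGTAC", "ACGTACGTAC")
        assert [(h.start, h.end, h.mismatches) for h in hits] == [(1, 10, 0)]

    def test_five_exact_copies(self):
        hits = map_pattern("ACGTACGTAC" * 5, "ACGTACGTAC")
        assert [(h.start, h.end) for h in hits] == [
            (1 + 10 * i, 10 * (i + 1)) for i in range(5)
        ]

    def test_budget_arithmetic(self, rng):
        pattern = random_seq(rng, 10)
        region = random_seq(rng, 400)
        for h in scan_pattern(region, pattern, 0.2):
            assert h.mismatches <= 2

    def test_scan_matches_brute_force(self, rng):
        monomer = generate_monomer(37, seed=7)
        region, _ = generate_array(monomer, 30, sub_rate=0.05, seed=7)
        got = [(h.start, h.mismatches) for h in scan_pattern(region, monomer, 0.2)]
        assert got == oracles.brute_hamming_hits(region, monomer, 0.2)

    def test_resolved_hits_never_overlap(self, rng):
        monomer = generate_monomer(20, seed=9)
        region, _ = generate_array(monomer, 40, sub_rate=0.08, seed=9)
        hits = map_pattern(region, monomer, 0.3)
        for a, b in zip(hits, hits[1:]):
            assert a.end < b.start


class TestSelectBestCandidate:
    def test_single_candidate(self):
        hs = [("A" * 10, [PatternHit(1, 10, 0)])]
        assert select_best_candidate(hs)[0] == "A" * 10

    def test_coverage_wins(self):
        a = ("AAA", [PatternHit(1, 90, 5)])
        b = ("CCC", [PatternHit(1, 60, 0)])
        assert select_best_candidate([b, a])[0] == "AAA"

    def test_tie_breaks_on_mismatches(self):
        a = ("AAA", [PatternHit(1, 50, 1)])
        b = ("CCC", [PatternHit(1, 50, 3)])
        assert select_best_candidate([b, a])[0] == "AAA"

    def test_all_empty_raises(self):
        with pytest.raises(NoMappableMonomer):
            select_best_candidate([("AAA", []), ("CCC", [])])


class TestConsensusFromHits:
    def test_identical_sequences(self, aligner):
        seqs = ["ACGTACGTTG"] * 10
        assert consensus_from_hits(seqs, aligner).sequence == "ACGTACGTTG"

    def test_single_substitution_outvoted(self, aligner):
        monomer = generate_monomer(60, seed=11)
        mutant = "A" + monomer[1:] if monomer[0] != "A" else "C" + monomer[1:]
        seqs = [monomer] * 9 + [mutant]
        assert consensus_from_hits(seqs, aligner).sequence == monomer

    def test_insertion_column_dropped(self, aligner):
        monomer = generate_monomer(60, seed=12)
        with_ins = monomer[:30] + "GG" + monomer[30:]
        seqs = [monomer, monomer, with_ins]
        assert consensus_from_hits(seqs, aligner).sequence == monomer

    def test_permutation_invariant(self, aligner, rng):
        monomer = generate_monomer(40, seed=13)
        seqs, _ = generate_array(monomer, 8, sub_rate=0.05, seed=13)
        seqs = [seqs[i * 40:(i + 1) * 40] for i in range(8)]
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert (
            consensus_from_hits(seqs, aligner).sequence
            == consensus_from_hits(shuffled, aligner).sequence
        )


class TestSplitUnmapped:
    REGION = RepetitiveRegion("s", 1001, 2000, 1)

    def test_full_coverage_no_split(self):
        assert split_unmapped(self.REGION, [PatternHit(1, 1000, 0)], 100) == []

    def test_uncovered_block_becomes_region(self):
        hits = [PatternHit(1, 400, 0)]
        out = split_unmapped(self.REGION, hits, 100)
        assert [(r.start, r.end) for r in out] == [(1401, 2000)]

    def test_boundary_exactly_min_unmapped_not_split(self):
        hits = [PatternHit(1, 500, 0), PatternHit(601, 1000, 0)]
        assert split_unmapped(self.REGION, hits, 100) == []
        hits = [PatternHit(1, 500, 0), PatternHit(602, 1000, 0)]
        out = split_unmapped(self.REGION, hits, 100)
        assert [(r.start, r.end) for r in out] == [(1501, 1601)]
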