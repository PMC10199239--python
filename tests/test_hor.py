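import numpy as np
import pytest

import oracles
from satkit import (
    HORParams,
    find_hors,
    find_hors_direct,
    find_hors_inverted,
    hor_period_proxy,
    repetitiveness_scores,
    variant_score_matrix,
)
from satkit.align import InternalAligner
from satkit.shifting import reverse_complement
from satkit.synth import generate_hor_array, generate_monomer


class TestVariantScoreMatrix:
    def test_identical_rows(self):
        m = variant_score_matrix(["ACT", "ACT"])
        assert m.vs(1, 2) == 0

    def test_single_disagreement(self):
        assert variant_score_matrix(["ACT", "AGT"]).vs(1, 2) == 1

    def test_gap_vs_base_counts_gap_vs_gap_does_not(self):
        assert variant_score_matrix(["A-T", "AGT"]).vs(1, 2) == 1
        assert variant_score_matrix(["A-T", "A-T"]).vs(1, 2) == 0

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            variant_score_matrix(["ACT", "AC"])


def _random_vs_matrix(rng, n, hi=10):
    vals = rng.integers(0, hi, size=(n, n))
    vals = np.triu(vals, 1)
    vals = vals + vals.T
    from satkit.hor import VSMatrix

    return VSMatrix(n=n, values=vals, alignment_length=100)


class TestDirectHORs:
    def test_no_pairs_below_threshold(self, rng):
        m = _random_vs_matrix(rng, 10, hi=10)
        m.values[m.values < 6] = 6
        np.fill_diagonal(m.values, 0)
        assert find_hors_direct(m, HORParams(3, 5)) == []

    def test_xyz_repeated_four_times(self):
        """12 monomers = XYZ repeated 4x with identical copies: maximal runs
        at offsets 3 (9 pairs), 6 (6 pairs) and 9 (3 pairs)."""
        from satkit.hor import VSMatrix

        n = 12
        vals = np.full((n, n), 50)
        for i in range(n):
            for j in range(n):
                if i != j and (i - j) % 3 == 0:
                    vals[i, j] = 0
        np.fill_diagonal(vals, 0)
        hors = find_hors_direct(VSMatrix(n, vals, 100), HORParams(3, 5))
        got = {(h.block1_start_idx, h.period, h.length) for h in hors}
        assert got == {(1, 3, 9), (1, 6, 6), (1, 9, 3)}

    def test_run_shorter_than_LM_not_reported(self):
        from satkit.hor import VSMatrix

        n = 6
        vals = np.full((n, n), 50)
        np.fill_diagonal(vals, 0)
        # exactly LM-1 = 2 qualifying pairs at offset 3
        vals[0, 3] = vals[3, 0] = 1
        vals[1, 4] = vals[4, 1] = 1
        hors = find_hors_direct(VSMatrix(n, vals, 100), HORParams(3, 5))
        assert hors == []

    def test_matches_brute_force(self, rng):
        for n in (5, 12, 25, 40):
            m = _random_vs_matrix(rng, n, hi=8)
            hors = find_hors_direct(m, HORParams(3, 5))
            got = {(h.block1_start_idx, h.period, h.length) for h in hors}
            assert got == oracles.brute_direct_hors(m.values, 3, 5)

    def test_total_vs_consistent(self, rng):
        m = _random_vs_matrix(rng, 20, hi=8)
        for h in find_hors_direct(m, HORParams(3, 5)):
            members = [
                m.vs(h.block1_start_idx + t, h.block2_start_idx + t)
                for t in range(h.length)
            ]
            assert all(v <= 5 for v in members)
            assert h.total_VS == sum(members)
            assert h.length >= 3

    def test_monotonic_in_parameters(self, rng):
        m = _random_vs_matrix(rng, 25, hi=8)
        strict = find_hors_direct(m, HORParams(4, 3))
        loose = find_hors_direct(m, HORParams(3, 5))

        def covered(h, hs):
            return any(
                o.period == h.period
                and o.block1_start_idx <= h.block1_start_idx
                and o.block1_start_idx + o.length >= h.block1_start_idx + h.length
                for o in hs
            )

        assert all(covered(h, loose) for h in strict)


class TestInvertedHORs:
    def test_no_opposite_strands_no_hors(self, rng):
        m = _random_vs_matrix(rng, 12, hi=2)
        assert find_hors_inverted(m, HORParams(3, 5), ["+"] * 12) == []

    def test_block_plus_reverse_complement_copy(self, aligner):
        """Four monomer variants followed by their reverse-complemented block:
        one inverted HOR pairing monomer i with monomer 9-i."""
        monomer = generate_monomer(178, seed=60)
        seq, truth = generate_hor_array(
            monomer, period=4, n_blocks=2, within_block_divergence=0.04,
            between_block_divergence=0.0, orientation="inverted", seed=60,
        )
        seqs, strands = [], []
        for c in truth.copies:
            piece = seq[c.start - 1:c.end]
            strands.append(c.strand)
            seqs.append(piece if c.strand == "+" else reverse_complement(piece))
        msa = aligner.msa(seqs)
        m = variant_score_matrix(msa)
        hors = find_hors_inverted(m, HORParams(3, 5), strands)
        assert any(
            h.length == 4 and h.block1_start_idx == 1 and h.block2_start_idx == 5
            for h in hors
        )

    def test_matches_brute_force(self, rng):
        for n in (6, 15, 30, 40):
            m = _random_vs_matrix(rng, n, hi=8)
            strands = [str(s) for s in rng.choice(["+", "-"], size=n)]
            got = {
                (h.block1_start_idx, h.block2_start_idx + h.length - 1, h.length)
                for h in find_hors_inverted(m, HORParams(3, 5), strands)
            }
            assert got == oracles.brute_inverted_hors(m.values, strands, 3, 5)

    def test_symmetric_under_reversal(self, rng):
        """Reversing the monomer order maps inverted HORs onto each other."""
        n = 20
        m = _random_vs_matrix(rng, n, hi=8)
        strands = [str(s) for s in rng.choice(["+", "-"], size=n)]
        fwd = find_hors_inverted(m, HORParams(3, 5), strands)
        m_rev = type(m)(n, m.values[::-1, ::-1].copy(), m.alignment_length)
        rev = find_hors_inverted(m_rev, HORParams(3, 5), strands[::-1])
        got = {
            (h.block1_start_idx, h.block2_start_idx, h.length) for h in fwd
        }
        want = {
            (n - (h.block2_start_idx + h.length - 1) + 1,
             n - (h.block1_start_idx + h.length - 1) + 1, h.length)
            for h in rev
        }
        assert got == want


class TestPerMonomerSummaries:
    def _hor(self, b1, b2, length, period, orientation="direct"):
        from satkit.hor import HORInstance

        return HORInstance("f", orientation, b1, b2, length, period, 0)

    def test_repetitiveness(self):
        hors = [self._hor(1, 6, 5, 5), self._hor(2, 10, 3, 8)]
        scores = repetitiveness_scores(hors, 12)
        assert scores[0] == 5          # monomer 1: one HOR of length 5
        assert scores[1] == 8          # monomer 2: lengths 5 + 3
        assert scores[11] == 3         # monomer 12: block2 of the second HOR
        assert repetitiveness_scores([], 3) == [0, 0, 0]

    def test_period_proxy_minimum_and_mode(self):
        hors = [self._hor(1, 13, 4, 12), self._hor(1, 7, 4, 6)]
        proxy, modal = hor_period_proxy(hors, 20)
        assert proxy[0] == 6           # monomer 1 in both: min(12, 6)
        assert proxy[19] is None
        assert modal == 6

    def test_inverted_hors_excluded_from_proxy(self):
        hors = [self._hor(1, 10, 3, 9, orientation="inverted")]
        proxy, modal = hor_period_proxy(hors, 12)
        assert modal is None and all(p is None for p in proxy)


class TestFindHorsChunking:
    def _family(self, aligner):
        monomer = generate_monomer(100, seed=70)
        seq, truth = generate_hor_array(
            monomer, period=3, n_blocks=4, within_block_divergence=0.05,
            between_block_divergence=0.003, seed=70,
        )
        seqs = [seq[c.start - 1:c.end] for c in truth.copies]
        return seqs, ["+"] * len(seqs)

    def test_under_cap_identical_for_any_large_cap(self, aligner):
        seqs, strands = self._family(aligner)
        a, _ = find_hors(seqs, strands, HORParams(3, 5), aligner, chunk_cap=20000)
        b, _ = find_hors(seqs, strands, HORParams(3, 5), aligner, chunk_cap=len(seqs))
        assert a == b and len(a) > 0

    def test_chunked_hors_are_subruns_of_full(self, aligner):
        """Over the cap, chunks may truncate maximal runs at chunk borders,
        but every chunked HOR must be a sub-run of a full-analysis HOR."""
        seqs, strands = self._family(aligner)
        full, _ = find_hors(seqs, strands, HORParams(3, 5), aligner, chunk_cap=20000)
        chunked, _ = find_hors(seqs, strands, HORParams(3, 5), aligner, chunk_cap=8)
        direct_full = [h for h in full if h.orientation == "direct"]
        assert chunked
        for h in chunked:
            if h.orientation != "direct":
                continue
            assert any(
                o.period == h.period
                and o.block1_start_idx <= h.block1_start_idx
                and o.block1_start_idx + o.length
                >= h.block1_start_idx + h.length
                for o in direct_full
            )
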