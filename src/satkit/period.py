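"""Monomer period estimation, candidate mapping and the primary consensus.

Inside a region made of tandem copies of one monomer, identical k-mers recur
at spacings equal to the monomer period (and its multiples), so the modal
distance between consecutive occurrences of identical k-mers estimates the
period N.  Higher-order structure can shift the mode to a multiple of the
true monomer; an optional divisor scan splits such periods back down.
Random N-length samples of the region are then mapped back with a
fixed-length Hamming matcher, the best-covering sample's hits are aligned,
and their per-column majority gives the primary consensus.  Stretches the
consensus fails to cover re-enter the pipeline as fresh regions, which
resolves adjacent arrays of distinct families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .regions import RepetitiveRegion, _valid_kmer_mask

_ACGT = frozenset("ACGT")


class NoMappableMonomer(ValueError):
    """Raised when no sampled candidate maps anywhere in the region."""


@dataclass(frozen=True)
class PeriodEstimate:
    """Modal identical-k-mer spacing restricted to the admissible period range."""

    N: int
    histogram: Dict[int, int]
    mode_count: int


@dataclass
class PatternHit:
    """Fixed-length match of a pattern inside a region (1-based inclusive)."""

    start: int
    end: int
    mismatches: int
    strand: str = "+"
    pattern_id: int = 0


@dataclass(frozen=True)
class PrimaryConsensus:
    sequence: str
    support: int
    region: Optional[RepetitiveRegion] = None

    def __len__(self) -> int:
        return len(self.sequence)


def kmer_distance_histogram(region_seq: str, k: int = 10, max_monomer: int = 1000) -> Dict[int, int]:
    """Tally distances between consecutive occurrences of identical k-mers.

    Only consecutive (not all-pairs) occurrence distances are counted, which
    gives the same mode on tandem text with O(L) memory.  Distances above
    ``max_monomer`` are discarded; k-mers containing non-ACGT characters are
    ignored.  Regions shorter than 2k return an empty histogram.
    """
    s = region_seq.upper()
    L = len(s)
    if L < 2 * k:
        return {}
    valid = _valid_kmer_mask(s, k)
    last: Dict[str, int] = {}
    hist: Dict[int, int] = {}
    for i in range(L - k + 1):
        if not valid[i]:
            continue
        km = s[i:i + k]
        j = last.get(km)
        if j is not None:
            d = i - j
            if d <= max_monomer:
                hist[d] = hist.get(d, 0) + 1
        last[km] = i
    return hist


def estimate_period(
    histogram: Dict[int, int], min_monomer: int = 4, max_monomer: int = 1000
) -> Optional[PeriodEstimate]:
    """Most common k-mer distance within [min_monomer, max_monomer].

    Ties break toward the smallest distance.  Returns ``None`` when no
    distance falls inside the admissible range ("no repeat found").
    """
    restricted = {d: c for d, c in histogram.items() if min_monomer <= d <= max_monomer}
    if not restricted:
        return None
    N = min(restricted, key=lambda d: (-restricted[d], d))
    return PeriodEstimate(N=N, histogram=restricted, mode_count=restricted[N])


def maybe_split_period(
    histogram: Dict[int, int],
    N: int,
    threshold_pct: float = 100.0,
    max_div: int = 12,
    tol: Optional[int] = None,
) -> int:
    """Split a multi-monomer period N into its base monomer when warranted.

    For each integer divisor d in 2..max_div the histogram mass within
    +/-tol of round(N/d) is summed; d qualifies when that mass reaches
    ``threshold_pct`` percent of the count at N and, for composite d, every
    proper divisor of d also qualifies.  The largest qualifying d wins and
    round(N/d) is returned; otherwise N is returned unchanged.  At the
    default threshold of 100% the scan practically never fires.

    ``tol`` defaults to max(2, 2% of N/d) per divisor.
    """
    mode_count = histogram.get(N, 0)
    if mode_count == 0 or max_div < 2:
        return N
    need = (threshold_pct / 100.0) * mode_count

    def mass_near(target: int, d: int) -> int:
        t = tol if tol is not None else max(2, round(0.02 * N / d))
        return sum(c for dist, c in histogram.items() if abs(dist - target) <= t)

    qualifies: Dict[int, bool] = {}
    for d in range(2, max_div + 1):
        ok = mass_near(round(N / d), d) >= need
        if ok:
            for dp in range(2, d):
                if d % dp == 0 and not qualifies.get(dp, False):
                    ok = False
                    break
        qualifies[d] = ok
    winners = [d for d, ok in qualifies.items() if ok]
    if not winners:
        return N
    return round(N / max(winners))


def sample_candidates(
    region_seq: str, N: int, n_samples: int, rng: np.random.Generator
) -> List[str]:
    """Draw ``n_samples`` random N-length substrings of the region.

    Candidates containing non-ACGT characters are redrawn up to a bounded
    number of times and then skipped.  A region shorter than N is an error.
    """
    L = len(region_seq)
    if L < N:
        raise ValueError("region shorter than period")
    s = region_seq.upper()
    out: List[str] = []
    for _ in range(n_samples):
        for _attempt in range(25):
            pos = int(rng.integers(0, L - N + 1))
            cand = s[pos:pos + N]
            if set(cand) <= _ACGT:
                out.append(cand)
                break
    return out


def _mismatch_profile(seq: str, pattern: str) -> np.ndarray:
    """Hamming mismatch count of ``pattern`` at every start position of ``seq``."""
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(pattern.upper().encode("ascii"), dtype=np.uint8)
    n_pos = len(a) - len(p) + 1
    if n_pos <= 0:
        return np.zeros(0, dtype=np.int32)
    mism = np.zeros(n_pos, dtype=np.int32)
    for j in range(len(p)):
        mism += a[j:j + n_pos] != p[j]
    return mism


def scan_pattern(
    region_seq: str, pattern: str, max_mismatch_frac: float = 0.2,
    strand: str = "+", pattern_id: int = 0,
) -> List[PatternHit]:
    """All fixed-length occurrences within the mismatch budget, unresolved.

    The budget is floor(max_mismatch_frac * |pattern|) Hamming mismatches;
    no indels.  Overlapping hits are *not* resolved here.
    """
    m = len(pattern)
    budget = int(max_mismatch_frac * m)
    mism = _mismatch_profile(region_seq, pattern)
    starts = np.nonzero(mism <= budget)[0]
    return [
        PatternHit(int(s) + 1, int(s) + m, int(mism[s]), strand, pattern_id)
        for s in starts
    ]


def resolve_overlaps(candidates: List[PatternHit]) -> List[PatternHit]:
    """Greedy left-to-right overlap resolution: fewest mismatches, then leftmost.

    Candidates are processed in start order; a candidate overlapping the
    last accepted hit replaces it only when it has strictly fewer
    mismatches (so ties keep the leftmost hit).
    """
    ordered = sorted(candidates, key=lambda h: (h.start, h.mismatches, h.strand))
    accepted: List[PatternHit] = []
    for cand in ordered:
        if accepted and cand.start <= accepted[-1].end:
            if cand.mismatches < accepted[-1].mismatches:
                accepted[-1] = cand
        else:
            accepted.append(cand)
    return accepted


def map_pattern(
    region_seq: str, pattern: str, max_mismatch_frac: float = 0.2
) -> List[PatternHit]:
    """Non-overlapping fixed-length occurrences of ``pattern`` in the region."""
    return resolve_overlaps(scan_pattern(region_seq, pattern, max_mismatch_frac))


def map_pattern_both_strands(
    region_seq: str, pattern: str, max_mismatch_frac: float = 0.2
) -> List[PatternHit]:
    """Map ``pattern`` and its reverse complement jointly.

    Hits record which orientation matched in ``strand``; overlaps between
    the two orientations are resolved with the same greedy rule.
    """
    from .shifting import reverse_complement

    fwd = scan_pattern(region_seq, pattern, max_mismatch_frac, "+")
    rev = scan_pattern(region_seq, reverse_complement(pattern), max_mismatch_frac, "-")
    return resolve_overlaps(fwd + rev)


def select_best_candidate(
    hit_sets: Sequence[Tuple[str, List[PatternHit]]]
) -> Tuple[str, List[PatternHit]]:
    """Candidate whose (non-overlapping) hits cover the most region bases.

    Ties break toward fewer total mismatches, then sampling order.  All
    candidates mapping nowhere is an error.
    """
    if not hit_sets:
        raise NoMappableMonomer("no candidates supplied")
    best = None
    best_key = None
    for idx, (cand, hits) in enumerate(hit_sets):
        cov = sum(h.end - h.start + 1 for h in hits)
        mm = sum(h.mismatches for h in hits)
        key = (-cov, mm, idx)
        if best_key is None or key < best_key:
            best_key = key
            best = (cand, hits)
    assert best is not None
    if not best[1]:
        raise NoMappableMonomer("no mappable monomer: all candidates yielded zero hits")
    return best


def consensus_from_hits(hit_sequences: Sequence[str], aligner) -> PrimaryConsensus:
    """Majority-rule consensus of the aligned hit sequences.

    Sequences are multiply aligned with ``aligner.msa``; per column the most
    frequent base wins (ties broken alphabetically A<C<G<T), columns whose
    strict majority character is a gap are dropped, and non-ACGT characters
    are treated as gaps.
    """
    if not hit_sequences:
        raise ValueError("consensus_from_hits requires at least one sequence")
    if len(hit_sequences) == 1:
        return PrimaryConsensus(hit_sequences[0].upper(), 1)
    rows = aligner.msa([s.upper() for s in hit_sequences])
    width = len(rows[0])
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(
        len(rows), width
    )
    out: List[str] = []
    bases = [ord(c) for c in "ACGT"]
    for col in arr.T:
        base_counts = [(int(np.sum(col == b)), chr(b)) for b in bases]
        best_count, best_base = max(base_counts, key=lambda t: (t[0], -ord(t[1])))
        gap_count = len(col) - sum(c for c, _ in base_counts)  # gaps + non-ACGT
        if best_count == 0 or gap_count > best_count:
            continue
        out.append(best_base)
    return PrimaryConsensus("".join(out), len(hit_sequences))


def split_unmapped(
    region: RepetitiveRegion, hits: Sequence[PatternHit], min_unmapped: int
) -> List[RepetitiveRegion]:
    """Unmapped stretches strictly longer than ``min_unmapped`` become new regions.

    ``hits`` carry coordinates relative to the region (1-based); returned
    regions are in genome coordinates and re-enter the pipeline.
    """
    L = region.width
    covered = np.zeros(L + 2, dtype=bool)
    for h in hits:
        covered[max(1, h.start): min(L, h.end) + 1] = True
    out: List[RepetitiveRegion] = []
    run_start = None
    for pos in range(1, L + 2):
        free = pos <= L and not covered[pos]
        if free and run_start is None:
            run_start = pos
        elif not free and run_start is not None:
            run_len = pos - run_start
            if run_len > min_unmapped:
                out.append(
                    RepetitiveRegion(
                        region.seq_id,
                        region.start + run_start - 1,
                        region.start + pos - 2,
                        0,
                    )
                )
            run_start = None
    return out
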