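"""Higher-order repeat (HOR) detection.

A HOR is a pair of equal-length monomer blocks whose position-matched
monomers are nearly identical.  All same-family monomers of an array are
multiply aligned and every monomer pair gets a *variant score* VS: the
number of alignment columns where the two rows differ (gap-vs-base counts,
gap-vs-gap does not).  In the resulting matrix a same-strand block
duplication appears as a run of small VS values along a diagonal offset d
(pairs (i, i+d)), and an inverted duplication as a run along an
anti-diagonal (pairs (i, j), (i+1, j-1), ... with opposite strands).
Maximal runs with every VS <= VS_max and at least LM pairs are reported,
one HOR per run.  Per-monomer summaries: *repetitiveness* sums the lengths
of all HORs a monomer belongs to, and the *period proxy* is the smallest
block-to-block distance among its direct HORs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class HORParams:
    """LM = minimal monomer pairs per HOR; VS_max = maximal per-pair VS."""

    LM: int = 3
    VS_max: int = 5

    def __post_init__(self):
        if self.LM < 2:
            raise ValueError("LM must be >= 2")
        if self.VS_max < 0:
            raise ValueError("VS_max must be >= 0")


@dataclass(frozen=True)
class VSMatrix:
    """Pairwise variant scores of n monomers from one family MSA."""

    n: int
    values: np.ndarray          # (n, n) symmetric int matrix, zero diagonal
    alignment_length: int

    def vs(self, i: int, j: int) -> int:
        """Variant score of 1-based monomer indices i, j."""
        return int(self.values[i - 1, j - 1])


@dataclass(frozen=True)
class HORInstance:
    """A detected block duplication.

    Monomer indices are 1-based into the analysed monomer list.  For direct
    HORs block2 sits ``period`` monomers downstream of block1 and the pairs
    are (b1+t, b2+t); for inverted HORs the pairs are (b1+t, b2_end-t), i.e.
    block2 is the reverse-complemented copy of block1.
    """

    family: str
    orientation: str            # "direct" | "inverted"
    block1_start_idx: int
    block2_start_idx: int
    length: int
    period: int
    total_VS: int

    @property
    def block1_range(self) -> Tuple[int, int]:
        return self.block1_start_idx, self.block1_start_idx + self.length - 1

    @property
    def block2_range(self) -> Tuple[int, int]:
        return self.block2_start_idx, self.block2_start_idx + self.length - 1


def variant_score_matrix(msa: Sequence[str]) -> VSMatrix:
    """Pairwise disagreement counts over the rows of a family MSA.

    Gap-vs-base differences count as disagreements; gap-vs-gap columns do
    not (two gaps are the same character).  Rows must share one length.
    """
    if len(msa) < 2:
        raise ValueError("variant_score_matrix requires >= 2 aligned rows")
    width = len(msa[0])
    if any(len(r) != width for r in msa):
        raise ValueError("ragged alignment rows")
    arr = np.frombuffer("".join(r.upper() for r in msa).encode("ascii"),
                        dtype=np.uint8).reshape(len(msa), width)
    n = len(msa)
    vals = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        vals[i, i + 1:] = np.sum(arr[i + 1:] != arr[i], axis=1)
    vals = vals + vals.T
    return VSMatrix(n=n, values=vals, alignment_length=width)


def _runs(ok: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (start_index, length), 0-based."""
    out = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(ok) - start))
    return out


def find_hors_direct(matrix: VSMatrix, params: HORParams, family: str = "") -> List[HORInstance]:
    """Same-strand HORs: runs along diagonal offsets of the VS matrix.

    For each offset d >= 1 the pairs (i, i+d) are scanned in order; every
    maximal run of consecutive pairs with VS <= VS_max and at least LM
    pairs is one HOR with period d.  Monomers may belong to several HORs
    and, when d < length, the two blocks of one HOR overlap.
    """
    n = matrix.n
    out: List[HORInstance] = []
    for d in range(1, n):
        diag = np.diagonal(matrix.values, offset=d)
        for start0, length in _runs(diag <= params.VS_max):
            if length >= params.LM:
                total = int(diag[start0:start0 + length].sum())
                out.append(HORInstance(
                    family=family, orientation="direct",
                    block1_start_idx=start0 + 1,
                    block2_start_idx=start0 + 1 + d,
                    length=length, period=d, total_VS=total,
                ))
    return out


def find_hors_inverted(
    matrix: VSMatrix,
    params: HORParams,
    strands: Sequence[str],
    family: str = "",
) -> List[HORInstance]:
    """Opposite-strand HORs: runs along anti-diagonals of the VS matrix.

    Pairs on one anti-diagonal share i+j; consecutive pairs are (i, j),
    (i+1, j-1), ... moving inward.  A pair qualifies when VS <= VS_max and
    the two monomers sit on opposite genomic strands.  Runs of at least LM
    qualifying pairs are reported with orientation "inverted"; block2 holds
    the higher indices, so its monomers pair with block1 in reverse order.
    """
    n = matrix.n
    if len(strands) != n:
        raise ValueError("strands length must equal matrix size")
    out: List[HORInstance] = []
    for s in range(1 + 2, 2 * n):  # i + j (1-based) ranges over 3 .. 2n-1
        i_lo = max(1, s - n)
        i_hi = (s - 1) // 2
        if i_hi < i_lo:
            continue
        idx_i = np.arange(i_lo, i_hi + 1)
        idx_j = s - idx_i
        vs = matrix.values[idx_i - 1, idx_j - 1]
        opp = np.array([strands[i - 1] != strands[j - 1]
                        for i, j in zip(idx_i, idx_j)])
        ok = (vs <= params.VS_max) & opp
        for start0, length in _runs(ok):
            if length >= params.LM:
                i0 = int(idx_i[start0])
                j0 = int(idx_j[start0])
                total = int(vs[start0:start0 + length].sum())
                b2_start = j0 - length + 1
                out.append(HORInstance(
                    family=family, orientation="inverted",
                    block1_start_idx=i0,
                    block2_start_idx=b2_start,
                    length=length, period=b2_start - i0, total_VS=total,
                ))
    return out


def repetitiveness_scores(hors: Sequence[HORInstance], n_monomers: int) -> List[int]:
    """Per monomer: sum of the lengths of every HOR it appears in (either block)."""
    scores = [0] * n_monomers
    for h in hors:
        for lo, hi in (h.block1_range, h.block2_range):
            for m in range(lo, hi + 1):
                if 1 <= m <= n_monomers:
                    scores[m - 1] += h.length
    return scores


def hor_period_proxy(
    hors: Sequence[HORInstance], n_monomers: int
) -> Tuple[List[Optional[int]], Optional[int]]:
    """Per monomer: minimal block-to-block distance among its direct HORs.

    Returns (per-monomer proxies, modal proxy).  Monomers in no direct HOR
    get None; the modal summary is over monomers with a proxy, ties broken
    toward the smaller period, None when no monomer has one.
    """
    proxy: List[Optional[int]] = [None] * n_monomers
    for h in hors:
        if h.orientation != "direct":
            continue
        for lo, hi in (h.block1_range, h.block2_range):
            for m in range(lo, hi + 1):
                if 1 <= m <= n_monomers:
                    if proxy[m - 1] is None or h.period < proxy[m - 1]:
                        proxy[m - 1] = h.period
    present = [p for p in proxy if p is not None]
    if not present:
        return proxy, None
    counts = Counter(present)
    modal = min(counts, key=lambda p: (-counts[p], p))
    return proxy, modal


def find_hors(
    sequences: Sequence[str],
    strands: Sequence[str],
    params: HORParams,
    aligner,
    family: str = "",
    chunk_cap: int = 20000,
) -> Tuple[List[HORInstance], Optional[VSMatrix]]:
    """Align a family's monomers, build the VS matrix and report all HORs.

    Families larger than ``chunk_cap`` monomers are processed in
    overlapping chunks (size ``chunk_cap``, overlap ``chunk_cap // 2``) and
    the HOR lists deduplicated, since an all-versus-all MSA would be
    infeasible; inputs at or under the cap take the single-MSA path, so
    chunking cannot change their results.  HORs spanning further than the
    chunk overlap are not recoverable in chunked mode.  The matrix is
    returned only in unchunked mode.
    """
    n = len(sequences)
    if n < 2:
        return [], None
    if n <= chunk_cap:
        msa = aligner.msa(sequences)
        matrix = variant_score_matrix(msa)
        hors = find_hors_direct(matrix, params, family)
        hors += find_hors_inverted(matrix, params, strands, family)
        return hors, matrix
    step = chunk_cap // 2
    seen: Dict[Tuple, HORInstance] = {}
    for chunk_start in range(0, n - step, step):
        lo = chunk_start
        hi = min(n, chunk_start + chunk_cap)
        sub_msa = aligner.msa(sequences[lo:hi])
        matrix = variant_score_matrix(sub_msa)
        sub = find_hors_direct(matrix, params, family)
        sub += find_hors_inverted(matrix, params, strands[lo:hi], family)
        for h in sub:
            shifted = HORInstance(
                family=h.family, orientation=h.orientation,
                block1_start_idx=h.block1_start_idx + lo,
                block2_start_idx=h.block2_start_idx + lo,
                length=h.length, period=h.period, total_VS=h.total_VS,
            )
            key = (shifted.orientation, shifted.block1_start_idx,
                   shifted.block2_start_idx, shifted.length)
            prev = seen.get(key)
            if prev is None or shifted.total_VS < prev.total_VS:
                seen[key] = shifted
        if hi == n:
            break
    return sorted(
        seen.values(),
        key=lambda h: (h.orientation, h.period, h.block1_start_idx, h.length),
    ), None
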