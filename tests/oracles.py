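"""Independent brute-force oracles used by the test suite.

Each function reimplements an operation in the most literal way possible
(enumeration, quadratic DP, direct set/interval arithmetic) so the package
can be checked against code that shares none of its implementation.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

_VAL = {"A": 0, "C": 1, "T": 2, "G": 3}


def brute_score_window(window: str, k: int) -> float:
    w = window.upper()
    L = len(w)
    if L < k:
        return 0.0
    kmers = [w[i:i + k] for i in range(L - k + 1)]
    ok = [set(km) <= set("ACGT") for km in kmers]
    tally = 0
    for i, km in enumerate(kmers):
        if not ok[i]:
            continue
        if sum(1 for j, other in enumerate(kmers) if ok[j] and other == km) >= 2:
            tally += 1
    return tally / L


def brute_otsu(scores: Sequence[float], n_bins: int) -> float | None:
    """Exhaustive between-class-variance maximizer on the same binning."""
    s = np.clip(np.asarray(scores, float), 0, 1)
    if np.all(s == s[0]):
        return None
    hist, edges = np.histogram(s, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    best_sigma, best_thr = None, None
    for b in range(n_bins - 1):
        lo = hist[: b + 1]
        hi = hist[b + 1:]
        w0, w1 = lo.sum(), hi.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float(np.dot(lo, centers[: b + 1])) / w0
        mu1 = float(np.dot(hi, centers[b + 1:])) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if best_sigma is None or sigma > best_sigma:
            best_sigma, best_thr = sigma, edges[b + 1]
    if best_thr is None:
        return None
    return float(best_thr)


def brute_hash_6mer(hexamer: str) -> int:
    return sum(_VAL[c] * 4 ** (i + 1) for i, c in enumerate(hexamer.upper()))


def brute_shift_score(seq: str) -> int:
    n = len(seq)
    ext = (seq * ((6 // n) + 2))  # long enough for wrap-around hexamers
    return sum((j + 1) * brute_hash_6mer(ext[j:j + 6]) for j in range(n))


def brute_hamming_hits(seq: str, pattern: str, max_mismatch_frac: float) -> List[Tuple[int, int]]:
    """(1-based start, mismatches) of all in-budget fixed-length occurrences."""
    s, p = seq.upper(), pattern.upper()
    m = len(p)
    budget = int(max_mismatch_frac * m)
    out = []
    for i in range(len(s) - m + 1):
        mm = sum(1 for a, b in zip(s[i:i + m], p) if a != b)
        if mm <= budget:
            out.append((i + 1, mm))
    return out


def dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_direct_hors(values: np.ndarray, LM: int, VS_max: int) -> Set[Tuple[int, int, int]]:
    """All direct HORs as (block1_start, period, length), 1-based, by scanning
    every (i, d) pair and keeping maximal qualifying runs."""
    n = values.shape[0]
    out = set()
    for d in range(1, n):
        i = 1
        while i + d <= n:
            if values[i - 1, i + d - 1] <= VS_max:
                start = i
                while i + d <= n and values[i - 1, i + d - 1] <= VS_max:
                    i += 1
                length = i - start
                if length >= LM:
                    out.add((start, d, length))
            else:
                i += 1
    return out


def brute_inverted_hors(
    values: np.ndarray, strands: Sequence[str], LM: int, VS_max: int
) -> Set[Tuple[int, int, int]]:
    """All inverted HORs as (i0, j0, length): runs of (i0+t, j0-t) pairs with
    VS <= VS_max and opposite strands, maximal, at least LM pairs."""
    n = values.shape[0]

    def ok(i, j):
        return (
            values[i - 1, j - 1] <= VS_max and strands[i - 1] != strands[j - 1]
        )

    out = set()
    for s in range(3, 2 * n):
        pairs = [(i, s - i) for i in range(max(1, s - n), (s - 1) // 2 + 1)]
        t = 0
        while t < len(pairs):
            if ok(*pairs[t]):
                start = t
                while t < len(pairs) and ok(*pairs[t]):
                    t += 1
                if t - start >= LM:
                    out.add((pairs[start][0], pairs[start][1], t - start))
            else:
                t += 1
    return out


def kmer_set_circular(seq: str, k: int) -> Set[str]:
    ext = (seq * (k + 1))[: len(seq) + k - 1]
    return {ext[i:i + k] for i in range(len(seq))}
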