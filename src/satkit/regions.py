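"""Repetitive-region discovery.

A sequence is tiled with fixed-size windows and each window receives a
*repeat-content score*: the proportion of positions whose k-mer occurs at
least twice inside the window, relative to the window length.  Windows of
unique sequence score near 0 while windows inside tandem arrays score
roughly 0.8-1.0, so the score distribution of a genome is strongly bimodal.
Otsu's method (the classic histogram-based image thresholding criterion)
separates the two modes; windows above the threshold are marked repetitive
and physically adjacent repetitive windows are merged into regions, which
are the unit of all downstream per-array analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class WindowScore:
    """Repeat-content score of one genomic window (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    score: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepetitiveRegion:
    """Merged run of adjacent repetitive windows (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    source_windows: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def _valid_kmer_mask(window: str, k: int) -> np.ndarray:
    """Boolean mask over k-mer start positions: True iff the k-mer is pure ACGT."""
    bad = np.fromiter((c not in _ACGT for c in window), dtype=np.int32, count=len(window))
    cum = np.concatenate(([0], np.cumsum(bad)))
    n = len(window) - k + 1
    return (cum[k:] - cum[:n]) == 0


def score_window(window: str, k: int = 10) -> float:
    """Fraction of positions whose k-mer occurs >= 2 times within the window.

    The denominator is the window length, so even a perfectly repetitive
    window scores slightly below 1 (the trailing k-1 positions start no
    k-mer).  k-mers containing non-ACGT characters never count as repeated.
    A window shorter than ``k`` scores 0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    L = len(window)
    if L < k:
        warnings.warn(f"window of length {L} shorter than k={k}; score set to 0")
        return 0.0
    w = window.upper()
    valid = _valid_kmer_mask(w, k)
    counts: Dict[str, int] = {}
    kmers = [w[i:i + k] for i in range(L - k + 1)]
    for i, km in enumerate(kmers):
        if valid[i]:
            counts[km] = counts.get(km, 0) + 1
    non_unique = sum(1 for i, km in enumerate(kmers) if valid[i] and counts[km] >= 2)
    return non_unique / L


def compute_window_scores(
    sequence: str, seq_id: str, window_size: int = 1500, k: int = 10
) -> List[WindowScore]:
    """Tile ``sequence`` with consecutive non-overlapping windows and score each.

    The final window may be shorter than ``window_size``; its score uses its
    own length as denominator.  Empty input yields an empty list.
    """
    out: List[WindowScore] = []
    L = len(sequence)
    for s0 in range(0, L, window_size):
        e0 = min(s0 + window_size, L)
        out.append(
            WindowScore(seq_id, s0 + 1, e0, score_window(sequence[s0:e0], k))
        )
    return out


def otsu_threshold(scores: Sequence[float], n_bins: int = 256) -> Optional[float]:
    """Otsu threshold of the binned score histogram on [0, 1].

    Scores are histogrammed into ``n_bins`` equal-width bins and the split
    maximizing the between-class variance is found exhaustively.  The
    returned threshold is the lower edge of the first bin of the upper
    class, so classification with ``score >= threshold`` reproduces the
    optimal split exactly.

    Returns ``None`` (the "no split" sentinel) when the distribution is
    degenerate: all scores identical, or all mass in a single bin.  Fewer
    than two scores is an error; the caller should fall back to an absolute
    floor.
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size < 2:
        raise ValueError("otsu_threshold requires at least two scores")
    if np.all(s == s[0]):
        return None
    hist, edges = np.histogram(np.clip(s, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)[:-1]                       # mass of bins 0..b
    w1 = total - w0
    m = np.cumsum(hist * centers)
    mu0 = np.divide(m[:-1], w0, out=np.zeros_like(centers[:-1]), where=w0 > 0)
    mu1 = np.divide(m[-1] - m[:-1], w1, out=np.zeros_like(centers[:-1]), where=w1 > 0)
    sigma_b = w0.astype(float) * w1.astype(float) * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None
    sigma_b[~valid] = -1.0
    b = int(np.argmax(sigma_b))  # first maximum -> lowest threshold, deterministic
    return float(edges[b + 1])


def merge_repetitive_windows(
    windows: Sequence[WindowScore],
    threshold: Optional[float],
    floor: float = 0.5,
) -> List[RepetitiveRegion]:
    """Merge maximal runs of adjacent repetitive windows into regions.

    A window is repetitive iff its score >= max(threshold, floor); with the
    degenerate ``threshold=None`` sentinel only the floor applies.  Windows
    must be sorted by start within each seq_id; adjacency means the next
    window starts exactly one base after the previous ends.
    """
    eff = floor if threshold is None else max(threshold, floor)
    regions: List[RepetitiveRegion] = []
    cur: Optional[List] = None  # [seq_id, start, end, count]
    for w in windows:
        rep = w.score >= eff
        if rep and cur is not None and w.seq_id == cur[0] and w.start == cur[2] + 1:
            cur[2] = w.end
            cur[3] += 1
        elif rep:
            if cur is not None:
                regions.append(RepetitiveRegion(*cur))
            cur = [w.seq_id, w.start, w.end, 1]
        else:
            if cur is not None:
                regions.append(RepetitiveRegion(*cur))
                cur = None
    if cur is not None:
        regions.append(RepetitiveRegion(*cur))
    return regions
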