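"""Monomer polishing, family consensus and per-monomer edit distances.

After the secondary mapping, neighbouring hits may overlap slightly (the
matcher is fixed-length while real copies drift by indels) or leave tiny
gaps.  Short overlaps are split evenly between the two hits, long overlaps
(at least half the consensus length) drop the shorter hit, and gaps of up
to a few bases are closed by extending both neighbours.  Classified repeats
are then re-aligned per family and each monomer gets a Levenshtein edit
distance to the family consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import edlib

from .period import PatternHit, consensus_from_hits


@dataclass
class RepeatHit:
    """One annotated monomer in genome coordinates (1-based inclusive).

    ``sequence`` is stored in the monomer's own reading orientation, i.e.
    the reverse complement of the genomic slice for '-' strand hits, so
    same-family monomers are directly comparable.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    sequence: str = ""
    region_id: str = ""
    family: Optional[str] = None
    edit_distance: Optional[int] = None
    repetitiveness: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def polish_hits(
    hits: Sequence[PatternHit],
    consensus_len: int,
    max_gap_fill: int = 4,
    region_seq: Optional[str] = None,
) -> List[PatternHit]:
    """Resolve residual overlaps and close short gaps between adjacent hits.

    For each adjacent pair (hits sorted by start):

    * overlap ``o`` with 0 < o < consensus_len/2: the upstream end moves
      back by ceil(o/2) and the downstream start forward by floor(o/2);
    * overlap ``o`` >= consensus_len/2: the shorter hit is removed
      (equal lengths remove the downstream hit);
    * gap ``g`` with 1 <= g <= max_gap_fill: the upstream hit extends by
      ceil(g/2) and the downstream hit starts floor(g/2) earlier;
    * larger gaps are untouched.

    Hits trimmed to nothing are dropped.  When ``region_seq`` is given the
    hit coordinates are clamped to it (1..len).  Idempotent.
    """
    out: List[PatternHit] = [
        PatternHit(h.start, h.end, h.mismatches, h.strand, h.pattern_id)
        for h in sorted(hits, key=lambda h: (h.start, h.end))
    ]
    limit = len(region_seq) if region_seq is not None else None
    i = 0
    while i < len(out) - 1:
        up, dn = out[i], out[i + 1]
        if (dn.start, dn.end) < (up.start, up.end):
            # coordinate edits on nested input can invert local order
            out[i], out[i + 1] = dn, up
            i = max(0, i - 1)
            continue
        o = up.end - dn.start + 1
        if o > 0:
            if 2 * o >= consensus_len:
                up_len = up.end - up.start + 1
                dn_len = dn.end - dn.start + 1
                drop = i + 1 if dn_len <= up_len else i
                del out[drop]
                i = max(0, i - 1)  # new neighbour pair may need fixing
                continue
            up.end -= math.ceil(o / 2)
            dn.start += o // 2
            if up.end < up.start:
                del out[i]
            elif dn.end < dn.start:
                del out[i + 1]
            i = max(0, i - 1)  # trimming can open a fillable gap upstream
            continue
        g = dn.start - up.end - 1
        if 1 <= g <= max_gap_fill:
            up.end += math.ceil(g / 2)
            dn.start -= g // 2
        i += 1
    if limit is not None:
        for h in out:
            h.start = max(1, h.start)
            h.end = min(limit, h.end)
    return out


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def family_consensus_and_edits(
    sequences: Sequence[str], aligner, msa_cap: Optional[int] = None
) -> Tuple[str, List[int]]:
    """Family consensus plus each monomer's edit distance to it.

    The consensus uses the same majority rule as the primary consensus.
    ``msa_cap`` bounds the number of sequences entering the alignment (an
    evenly strided deterministic subset); edit distances are always
    computed for every input sequence.
    """
    if not sequences:
        raise ValueError("family_consensus_and_edits requires at least one repeat")
    seqs = [s.upper() for s in sequences]
    subset = seqs
    if msa_cap is not None and len(seqs) > msa_cap:
        stride = len(seqs) / msa_cap
        subset = [seqs[int(i * stride)] for i in range(msa_cap)]
    consensus = consensus_from_hits(subset, aligner).sequence
    dists = [levenshtein(consensus, s) for s in seqs]
    return consensus, dists
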