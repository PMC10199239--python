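"""Reading-frame canonicalization and family classification of consensuses.

Tandem monomers are circular strings: any rotation (on either strand) is an
equally valid representative, but mixing frames ruins downstream alignments.
Each rotation is scored with a positional hash: every circular 6-mer gets an
integer K = sum_i V_i * 4^i (A=0, C=1, T=2, G=3, i = 1..6) and the rotation
score is S = sum_j j * K_j over the 6-mers in order.  The rotation/strand
with minimal S is the canonical frame -- an arbitrary but deterministic
choice that is identical for every rotation of every strand of the same
circular sequence, so related monomers always end up in one frame.

Classification against user-supplied template families is alignment-free:
circular 8-mer sets are compared with the Jaccard index, and significance is
assessed against scores of character-shuffled queries.  A classified
consensus is finally re-rotated to the template's own frame by exhaustive
alignment of all rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

_VAL = {"A": 0, "C": 1, "T": 2, "G": 3}
_POW4 = np.array([4 ** i for i in range(1, 7)], dtype=np.int64)
_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ShiftEvaluation:
    """Outcome of frame canonicalization."""

    rotation_offset: int          # 0-based offset into the (possibly RC'd) sequence
    strand: str                   # "forward" | "reverse"
    S: int                        # shift score of the chosen rotation


@dataclass(frozen=True)
class TemplateFamily:
    """Named consensus used for family classification and frame alignment."""

    name: str
    consensus: str

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("template consensus must be non-empty")
        up = self.consensus.upper()
        if set(up) - set("ACGT"):
            raise ValueError(f"template {self.name!r} contains non-ACGT characters")
        object.__setattr__(self, "consensus", up)


@dataclass
class ClassificationResult:
    family: Optional[str]
    score: float
    significant: bool
    null_scores: List[float] = field(default_factory=list)
    best_template: Optional[str] = None


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_VAL[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc} in sequence") from exc


def hash_6mer(hexamer: str) -> int:
    """Positional hash K of one hexamer: sum of V_i * 4^i for i = 1..6.

    Injective over the 4096 ACGT hexamers; non-ACGT input is an error.
    """
    if len(hexamer) != 6:
        raise ValueError("hash_6mer requires exactly 6 characters")
    v = _encode(hexamer)
    return int(np.dot(v, _POW4))


def _circular_kmer_scores(v: np.ndarray) -> np.ndarray:
    """K_j for the circular 6-mer starting at every position of ``v``."""
    n = len(v)
    K = np.zeros(n, dtype=np.int64)
    for t in range(6):
        K += np.roll(v, -t) * int(_POW4[t])
    return K


def _rotation_scores(v: np.ndarray) -> np.ndarray:
    """Shift score S of every rotation of ``v`` (index = rotation offset).

    Uses the exact integer recurrence S(r+1) = S(r) - sum(K) + n*K[r], so
    all n rotations cost O(n) after the K scores.
    """
    n = len(v)
    K = _circular_kmer_scores(v)
    j = np.arange(1, n + 1, dtype=np.int64)
    s0 = np.int64(np.dot(j, K))
    total = np.int64(K.sum())
    if n == 1:
        return np.array([s0], dtype=np.int64)
    deltas = n * K[:-1] - total
    return np.concatenate(([np.int64(0)], np.cumsum(deltas))) + s0


def shift_score(seq: str) -> int:
    """S = sum_j j * K_j over the circular 6-mers of ``seq`` in order."""
    if not seq:
        raise ValueError("empty sequence")
    v = _encode(seq)
    K = _circular_kmer_scores(v)
    j = np.arange(1, len(v) + 1, dtype=np.int64)
    return int(np.dot(j, K))


def canonical_shift(seq: str) -> Tuple[str, ShiftEvaluation]:
    """Rotation/strand of ``seq`` minimizing the shift score.

    All n rotations of the sequence and of its reverse complement are
    evaluated; ties prefer the forward strand, then the smallest offset.
    The result is invariant under rotation and reverse complementation of
    the input.
    """
    if not seq:
        raise ValueError("empty sequence")
    fwd = seq.upper()
    rev = reverse_complement(fwd)
    s_f = _rotation_scores(_encode(fwd))
    s_r = _rotation_scores(_encode(rev))
    off_f = int(np.argmin(s_f))
    off_r = int(np.argmin(s_r))
    if s_f[off_f] <= s_r[off_r]:
        off, strand, base, score = off_f, "forward", fwd, int(s_f[off_f])
    else:
        off, strand, base, score = off_r, "reverse", rev, int(s_r[off_r])
    canonical = base[off:] + base[:off]
    return canonical, ShiftEvaluation(off, strand, score)


def circular_kmer_set(seq: str, k: int = 8) -> Set[str]:
    """Deduplicated set of the n wrap-around k-mers of ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n = len(s)
    reps = -(-(n + k - 1) // n)  # ceil
    ext = (s * reps)[: n + k - 1]
    return {ext[i:i + k] for i in range(n)}


def jaccard_similarity(a: str, b: str, k: int = 8) -> float:
    """Jaccard index of the circular k-mer sets of two sequences."""
    A = circular_kmer_set(a, k)
    B = circular_kmer_set(b, k)
    return len(A & B) / len(A | B)


def classify_consensus(
    consensus: str,
    templates: Sequence[TemplateFamily],
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> ClassificationResult:
    """Assign the consensus to the best-scoring template family, with a
    permutation significance test.

    The best template by circular 8-mer Jaccard similarity is selected; the
    call is significant when the observed score exceeds the empirical
    (1 - alpha) quantile of scores between ``n_perm`` character-shuffles of
    the query and that template.  Non-significant queries get family None.

    The consensus frame is canonicalized to an arbitrary strand, so the
    statistic is strand-aware: max of the Jaccard scores of the query and
    of its reverse complement against the template, for the observed query
    and for every shuffle alike.
    """
    if not templates:
        raise ValueError("at least one template required")
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for alpha = 0.05")
    rng = rng if rng is not None else np.random.default_rng(0)

    def stat(query: str, template: str) -> float:
        return max(
            jaccard_similarity(query, template),
            jaccard_similarity(reverse_complement(query), template),
        )

    scores = [(stat(consensus, t.consensus), t.name) for t in templates]
    best_score, best_name = max(scores, key=lambda t: (t[0], t[1]))
    best_template = next(t for t in templates if t.name == best_name)
    chars = np.array(list(consensus.upper()))
    null = []
    for _ in range(n_perm):
        shuffled = "".join(rng.permutation(chars))
        null.append(stat(shuffled, best_template.consensus))
    cutoff = float(np.quantile(null, 1.0 - alpha))
    significant = best_score > cutoff
    return ClassificationResult(
        family=best_name if significant else None,
        score=best_score,
        significant=significant,
        null_scores=null,
        best_template=best_name,
    )


def shift_to_template(consensus: str, template: str) -> Tuple[str, ShiftEvaluation]:
    """Rotation (either strand) of the consensus best aligning to the template.

    All rotations of the consensus and of its reverse complement are scored
    with global pairwise alignment (match +1, mismatch -1, gap -2); the
    highest-scoring rotation wins, ties preferring the forward strand, then
    the smallest offset.
    """
    from .align import pairwise_score

    fwd = consensus.upper()
    rev = reverse_complement(fwd)
    n = len(fwd)
    best = None
    for strand, base in (("forward", fwd), ("reverse", rev)):
        doubled = base + base
        for off in range(n):
            rot = doubled[off:off + n]
            sc = pairwise_score(rot, template.upper())
            key = (-sc, 0 if strand == "forward" else 1, off)
            if best is None or key < best[0]:
                best = (key, rot, ShiftEvaluation(off, strand, 0))
    assert best is not None
    return best[1], best[2]
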