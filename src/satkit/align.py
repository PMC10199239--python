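"""Alignment engines.

Two interchangeable multiple-sequence aligners sit behind one interface:

* ``InternalAligner`` -- deterministic center-star progressive alignment.
  The center sequence (minimal summed edit distance to all others) is
  aligned pairwise against every other sequence with global
  Needleman-Wunsch (match +1, mismatch -1, gap -2, via Bio.Align's C
  pairwise engine) and the pairwise alignments are merged on the center's
  coordinates ("once a gap, always a gap").  No external processes, fully
  reproducible; the default engine.
* ``MafftAligner`` -- thin subprocess wrapper around an external ``mafft``
  binary for users who prefer it on large families.

Monomer families here are near-identical sequences of similar length, the
regime where center-star output is essentially indistinguishable from a
full progressive aligner.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import List, Sequence

import edlib
from Bio import Align, SeqIO


def _make_pairwise() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_PAIRWISE = _make_pairwise()


def pairwise_score(a: str, b: str) -> float:
    """Global alignment score (match +1, mismatch -1, gap -2)."""
    return float(_PAIRWISE.score(a, b))


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """One deterministic optimal global alignment of two sequences."""
    aln = _PAIRWISE.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


class InternalAligner:
    """Center-star progressive multiple aligner (see module docstring)."""

    #: above this many sequences the center search samples a deterministic subset
    center_sample_cap: int = 150

    def msa(self, seqs: Sequence[str]) -> List[str]:
        seqs = [s.upper() for s in seqs]
        if not seqs:
            return []
        if len(seqs) == 1:
            return list(seqs)
        center_idx = self._pick_center(seqs)
        center = seqs[center_idx]
        m = len(center)
        pairs = []
        for i, s in enumerate(seqs):
            if i == center_idx:
                pairs.append(None)
            else:
                pairs.append(pairwise_align(center, s))
        # master insertion profile: gaps opened in the center before position p
        master = [0] * (m + 1)
        projections = []
        for pr in pairs:
            if pr is None:
                projections.append(None)
                continue
            c_aln, s_aln = pr
            ins = [[] for _ in range(m + 1)]
            match = [None] * m
            p = 0
            for cc, sc in zip(c_aln, s_aln):
                if cc == "-":
                    ins[p].append(sc)
                else:
                    match[p] = sc
                    p += 1
            projections.append((ins, match))
            for p in range(m + 1):
                if len(ins[p]) > master[p]:
                    master[p] = len(ins[p])
        rows = []
        for proj in projections:
            if proj is None:  # the center itself
                parts = []
                for p in range(m + 1):
                    parts.append("-" * master[p])
                    if p < m:
                        parts.append(center[p])
                rows.append("".join(parts))
                continue
            ins, match = proj
            parts = []
            for p in range(m + 1):
                parts.append("-" * (master[p] - len(ins[p])) + "".join(ins[p]))
                if p < m:
                    parts.append(match[p] if match[p] is not None else "-")
            rows.append("".join(parts))
        return rows

    def _pick_center(self, seqs: Sequence[str]) -> int:
        n = len(seqs)
        if n <= 2:
            return 0
        if n > self.center_sample_cap:
            stride = n / self.center_sample_cap
            idx = sorted({int(i * stride) for i in range(self.center_sample_cap)})
        else:
            idx = list(range(n))
        best, best_cost = idx[0], None
        for i in idx:
            cost = sum(_edit_distance(seqs[i], seqs[j]) for j in idx if j != i)
            if best_cost is None or cost < best_cost:
                best, best_cost = i, cost
        return best


class MafftAligner:
    """MSA via an external ``mafft`` binary.

    ``settings`` are passed through verbatim (e.g. ``["--kimura", "1",
    "--retree", "1"]``).  Raises ``RuntimeError`` when mafft is absent.
    """

    def __init__(self, settings: Sequence[str] = ("--kimura", "1", "--retree", "1")):
        if shutil.which("mafft") is None:
            raise RuntimeError("mafft binary not found on PATH")
        self.settings = list(settings)

    def msa(self, seqs: Sequence[str]) -> List[str]:
        if not seqs:
            return []
        if len(seqs) == 1:
            return [seqs[0].upper()]
        with tempfile.TemporaryDirectory() as tmp:
            fa = Path(tmp) / "in.fa"
            with open(fa, "w") as fh:
                for i, s in enumerate(seqs):
                    fh.write(f">s{i}\n{s}\n")
            res = subprocess.run(
                ["mafft", *self.settings, "--quiet", str(fa)],
                capture_output=True, text=True, check=True,
            )
            out = Path(tmp) / "out.fa"
            out.write_text(res.stdout)
            records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(out), "fasta")}
        return [records[f"s{i}"] for i in range(len(seqs))]


def get_aligner(mode: str = "internal"):
    """Aligner factory for PipelineConfig.aligner."""
    if mode == "internal":
        return InternalAligner()
    if mode == "external":
        return MafftAligner()
    raise ValueError(f"unknown aligner mode {mode!r}")
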