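"""Synthetic tandem-repeat genomes with known ground truth.

Generators for monomers, diverged tandem arrays, higher-order-repeat arrays
(direct and inverted block duplications) and whole genome fixtures with
unique flanking background.  Every generator is a pure function of its
arguments and seed, and each records a ``SyntheticTruth`` with per-copy
intervals, strands and applied mutations so annotations can be scored at
base level.  These fixtures emulate the *structure* of satellite arrays
(unit size, per-copy divergence, block duplication), not their evolutionary
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .shifting import reverse_complement
from .regions import score_window

_BASES = np.array(list("ACGT"))


@dataclass
class CopyTruth:
    """One monomer copy: interval (1-based, local to its sequence), strand,
    the variant index inside a HOR block (0 for plain arrays) and the
    mutations applied (op, position-in-copy, from, to)."""

    start: int
    end: int
    strand: str = "+"
    variant: int = 0
    mutations: List[Tuple[str, int, str, str]] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    monomer: str
    copies: List[CopyTruth] = field(default_factory=list)
    hor: Optional[Dict] = None            # {"period":…, "n_blocks":…, "orientation":…}
    background: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def array_span(self) -> Tuple[int, int]:
        return self.copies[0].start, self.copies[-1].end

    def shifted(self, offset: int) -> "SyntheticTruth":
        """Truth with all intervals moved by ``offset`` bases."""
        return SyntheticTruth(
            monomer=self.monomer,
            copies=[CopyTruth(c.start + offset, c.end + offset, c.strand,
                              c.variant, list(c.mutations)) for c in self.copies],
            hor=dict(self.hor) if self.hor else None,
            background=[(s + offset, e + offset) for s, e in self.background],
        )


def generate_monomer(length: int, seed: int) -> str:
    """Uniform random ACGT string, deterministic per (length, seed)."""
    if length < 4:
        raise ValueError("monomer length must be >= 4")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=length))


def _mutate_copy(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> Tuple[str, List[Tuple[str, int, str, str]]]:
    """Apply independent per-base substitutions and single-base indels.

    Indels are capped so the copy length stays within +/-5% of the
    original, keeping fixtures inside the similar-unit-size regime.
    """
    max_drift = max(1, round(0.05 * len(seq)))
    drift = 0
    out: List[str] = []
    muts: List[Tuple[str, int, str, str]] = []
    for i, c in enumerate(seq):
        r = rng.random()
        if r < sub_rate:
            new = str(rng.choice(_BASES[_BASES != c]))
            out.append(new)
            muts.append(("sub", i + 1, c, new))
        elif r < sub_rate + indel_rate:
            if rng.random() < 0.5 and drift > -max_drift:
                drift -= 1
                muts.append(("del", i + 1, c, ""))
            elif drift < max_drift:
                ins = str(rng.choice(_BASES))
                out.append(c)
                out.append(ins)
                drift += 1
                muts.append(("ins", i + 1, "", ins))
            else:
                out.append(c)
        else:
            out.append(c)
    return "".join(out), muts


def generate_array(
    monomer: str,
    n_copies: int,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[str, SyntheticTruth]:
    """Tandem array of independently mutated monomer copies."""
    if not 0 <= sub_rate <= 0.2 or not 0 <= indel_rate <= 0.2:
        raise ValueError("mutation rates must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(monomer=monomer.upper())
    parts: List[str] = []
    pos = 1
    for _ in range(n_copies):
        cp, muts = _mutate_copy(truth.monomer, sub_rate, indel_rate, rng)
        parts.append(cp)
        truth.copies.append(CopyTruth(pos, pos + len(cp) - 1, "+", 0, muts))
        pos += len(cp)
    return "".join(parts), truth


def generate_hor_array(
    monomer: str,
    period: int,
    n_blocks: int,
    within_block_divergence: float = 0.06,
    between_block_divergence: float = 0.005,
    orientation: str = "direct",
    seed: int = 0,
) -> Tuple[str, SyntheticTruth]:
    """Array with higher-order structure: a block of ``period`` distinct
    monomer variants duplicated ``n_blocks`` times.

    Variants derive from ``monomer`` with ``within_block_divergence``
    substitutions each (making them mutually distinguishable); every block
    copy applies fresh ``between_block_divergence`` substitutions (keeping
    position-matched monomers across blocks nearly identical).  With
    ``orientation="inverted"`` every odd block is the reverse complement of
    a fresh block copy, so its monomers appear in reversed order on the
    minus strand.
    """
    if period < 2 or n_blocks < 2:
        raise ValueError("period and n_blocks must be >= 2")
    if orientation not in ("direct", "inverted"):
        raise ValueError("orientation must be 'direct' or 'inverted'")
    rng = np.random.default_rng(seed)
    base = monomer.upper()
    variants = []
    for _ in range(period):
        v, _m = _mutate_copy(base, within_block_divergence, 0.0, rng)
        variants.append(v)
    truth = SyntheticTruth(
        monomer=base,
        hor={"period": period, "n_blocks": n_blocks, "orientation": orientation},
    )
    parts: List[str] = []
    pos = 1
    for b in range(n_blocks):
        block_copies = []
        for vi, v in enumerate(variants):
            cp, muts = _mutate_copy(v, between_block_divergence, 0.0, rng)
            block_copies.append((cp, vi, muts))
        invert = orientation == "inverted" and b % 2 == 1
        if invert:
            block_copies = [(reverse_complement(cp), vi, muts)
                            for cp, vi, muts in reversed(block_copies)]
        for cp, vi, muts in block_copies:
            parts.append(cp)
            truth.copies.append(
                CopyTruth(pos, pos + len(cp) - 1, "-" if invert else "+", vi, muts)
            )
            pos += len(cp)
    return "".join(parts), truth


def random_background(length: int, rng: np.random.Generator, window: int = 1500,
                      k: int = 10, max_score: float = 0.2) -> str:
    """Unique random sequence, rejection-sampled against window repeat scores.

    Guards negative controls: any tile scoring >= ``max_score`` (far below
    the pipeline's classification floor) triggers a redraw of the chunk.
    """
    out: List[str] = []
    remaining = length
    while remaining > 0:
        chunk_len = min(remaining, 10 * window)
        for _ in range(10):
            chunk = "".join(rng.choice(_BASES, size=chunk_len))
            scores = [
                score_window(chunk[i:i + window], k)
                for i in range(0, chunk_len, window)
                if chunk_len - i >= k
            ]
            if not scores or max(scores) < max_score:
                break
        out.append(chunk)
        remaining -= chunk_len
    return "".join(out)


@dataclass(frozen=True)
class ArraySpec:
    """One array inside a genome fixture; ``hor_period`` switches the
    generator from a plain tandem array to a HOR array."""

    monomer_length: int = 178
    n_copies: int = 50
    sub_rate: float = 0.01
    indel_rate: float = 0.0
    hor_period: Optional[int] = None
    hor_blocks: int = 4
    within_block_divergence: float = 0.06
    between_block_divergence: float = 0.005
    orientation: str = "direct"


@dataclass(frozen=True)
class GenomeSpec:
    seq_id: str = "chr_test"
    arrays: Tuple[ArraySpec, ...] = (ArraySpec(),)
    flank: int = 5000


@dataclass
class GenomeFixture:
    records: List[Tuple[str, str]]
    truths: Dict[str, List[SyntheticTruth]]   # seq_id -> truths in genome coords
    monomers: Dict[str, str]                  # array label -> monomer sequence


def generate_genome_fixture(
    specs: Sequence[GenomeSpec] | GenomeSpec, seed: int = 0
) -> GenomeFixture:
    """Multi-record genome: arrays embedded in unique background flanks."""
    if isinstance(specs, GenomeSpec):
        specs = [specs]
    fixture = GenomeFixture(records=[], truths={}, monomers={})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        parts: List[str] = []
        truths: List[SyntheticTruth] = []
        pos = 0
        bg = random_background(spec.flank, rng)
        parts.append(bg)
        pos += len(bg)
        for ai, aspec in enumerate(spec.arrays):
            mono_seed = int(rng.integers(0, 2 ** 31 - 1))
            monomer = generate_monomer(aspec.monomer_length, mono_seed)
            arr_seed = int(rng.integers(0, 2 ** 31 - 1))
            if aspec.hor_period is None:
                seq, truth = generate_array(
                    monomer, aspec.n_copies, aspec.sub_rate, aspec.indel_rate,
                    arr_seed,
                )
            else:
                seq, truth = generate_hor_array(
                    monomer, aspec.hor_period, aspec.hor_blocks,
                    aspec.within_block_divergence,
                    aspec.between_block_divergence,
                    aspec.orientation, arr_seed,
                )
            truths.append(truth.shifted(pos))
            fixture.monomers[f"{spec.seq_id}_array{ai}"] = monomer
            parts.append(seq)
            pos += len(seq)
            bg = random_background(spec.flank, rng)
            parts.append(bg)
            pos += len(bg)
        fixture.records.append((spec.seq_id, "".join(parts)))
        fixture.truths[spec.seq_id] = truths
    return fixture


def write_fixture(fixture: GenomeFixture, outdir: str | Path) -> Dict[str, Path]:
    """Write FASTA plus plain-text truth files (BED for copies, CSV for HORs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "fixture.fa",
        "bed": outdir / "truth_copies.bed",
        "csv": outdir / "truth_arrays.csv",
    }
    with open(paths["fasta"], "w") as fh:
        for sid, seq in fixture.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(paths["bed"], "w") as fh:
        for sid, truths in fixture.truths.items():
            for ti, truth in enumerate(truths):
                for c in truth.copies:
                    fh.write(f"{sid}\t{c.start - 1}\t{c.end}\tarray{ti}\t0\t{c.strand}\n")
    with open(paths["csv"], "w") as fh:
        fh.write("seq_id,array,monomer_length,n_copies,hor_period,hor_blocks,orientation\n")
        for sid, truths in fixture.truths.items():
            for ti, truth in enumerate(truths):
                hor = truth.hor or {}
                fh.write(
                    f"{sid},array{ti},{len(truth.monomer)},{len(truth.copies)},"
                    f"{hor.get('period', '')},{hor.get('n_blocks', '')},"
                    f"{hor.get('orientation', '')}\n"
                )
    return paths


def base_level_metrics(
    annotated: Sequence[Tuple[int, int]],
    truth: Sequence[Tuple[int, int]],
) -> Tuple[float, float]:
    """(recall, precision) of annotated intervals against truth intervals,
    both 1-based inclusive, at single-base resolution."""
    def to_set(intervals):
        s = set()
        for a, b in intervals:
            s.update(range(a, b + 1))
        return s

    ann = to_set(annotated)
    tru = to_set(truth)
    if not tru:
        return (1.0 if not ann else 0.0), (0.0 if ann else 1.0)
    inter = len(ann & tru)
    recall = inter / len(tru)
    precision = inter / len(ann) if ann else 0.0
    return recall, precision
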