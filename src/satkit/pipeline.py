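"""End-to-end annotation workflow.

Per sequence (sequences are independent and may run in parallel):
window scoring -> Otsu threshold -> repetitive regions -> per-region period
estimate, candidate sampling and primary consensus -> frame
canonicalization (plus template classification and template-frame shift
when templates are given) -> secondary mapping on both strands ->
overlap/gap polishing -> region splitting on unmapped stretches.  Family
consensuses and per-monomer edit distances are computed genome-wide, and
HOR analysis runs for a selected family or monomer-size class.

Determinism: every random draw derives from (config.seed, crc32(seq_id),
region start), so serial and parallel runs of the same input are
byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from collections import deque
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import get_aligner
from .config import PipelineConfig
from .hor import HORParams, find_hors, hor_period_proxy, repetitiveness_scores
from .io import HOR_COLUMNS, REGION_COLUMNS, REPEAT_COLUMNS, read_fasta
from .period import (
    NoMappableMonomer,
    PatternHit,
    consensus_from_hits,
    estimate_period,
    kmer_distance_histogram,
    map_pattern_both_strands,
    maybe_split_period,
    sample_candidates,
    scan_pattern,
    select_best_candidate,
    split_unmapped,
)
from .refine import RepeatHit, family_consensus_and_edits, polish_hits
from .regions import (
    RepetitiveRegion,
    compute_window_scores,
    merge_repetitive_windows,
    otsu_threshold,
)
from .shifting import (
    TemplateFamily,
    canonical_shift,
    classify_consensus,
    reverse_complement,
    shift_to_template,
)

log = logging.getLogger("satkit")


@dataclass
class RegionAnnotation:
    region: RepetitiveRegion
    region_id: str
    period: int
    raw_period: int
    consensus: str
    family: Optional[str]
    hits: List[RepeatHit]
    coverage: float


@dataclass
class PipelineResult:
    repeats: pd.DataFrame
    regions: pd.DataFrame
    windows: pd.DataFrame
    hors: Optional[pd.DataFrame] = None
    family_consensus: Dict[str, str] = field(default_factory=dict)
    hor_period_modal: Dict[Tuple[str, str], Optional[int]] = field(default_factory=dict)


def region_rng(seed: int, seq_id: str, start: int) -> np.random.Generator:
    """Deterministic per-region random stream, independent of execution order."""
    sid = zlib.crc32(seq_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, sid, start]))


def _annotate_region(
    seq: str,
    region: RepetitiveRegion,
    padded: Tuple[int, int],
    config: PipelineConfig,
    templates: Optional[Sequence[TemplateFamily]],
    aligner,
) -> Optional[RegionAnnotation]:
    """Annotate one region; returns None when no repeat structure is found."""
    lo, hi = padded  # 1-based inclusive, genome coords
    rseq = seq[lo - 1:hi]
    hist = kmer_distance_histogram(rseq, config.k, config.max_monomer)
    est = estimate_period(hist, config.min_monomer, config.max_monomer)
    if est is None or est.mode_count < config.min_period_support:
        log.debug("region %s:%d-%d: no admissible period", region.seq_id, region.start, region.end)
        return None
    N = maybe_split_period(
        est.histogram, est.N, config.N_max_div_threshold_pct, config.max_N_split
    )
    if len(rseq) < N:
        return None
    rng = region_rng(config.seed, region.seq_id, region.start)
    candidates = sample_candidates(rseq, N, config.n_samples, rng)
    if not candidates:
        return None
    hit_sets = [
        (c, [h for h in _map_resolved(rseq, c, config)]) for c in candidates
    ]
    try:
        best_cand, best_hits = select_best_candidate(hit_sets)
    except NoMappableMonomer:
        return None
    if len(best_hits) < 2:
        return None
    hit_seqs = [rseq[h.start - 1:h.end] for h in best_hits[: config.consensus_max_hits]]
    primary = consensus_from_hits(hit_seqs, aligner)
    if len(primary.sequence) < config.min_monomer:
        return None
    consensus, _shift = canonical_shift(primary.sequence)
    family: Optional[str] = None
    if templates:
        cls = classify_consensus(consensus, templates, config.n_perm, config.alpha, rng)
        if cls.significant and cls.family is not None:
            family = cls.family
            tpl = next(t for t in templates if t.name == family)
            consensus, _tpl_shift = shift_to_template(consensus, tpl.consensus)
    sec_hits = map_pattern_both_strands(rseq, consensus, config.max_mismatch_frac)
    if len(sec_hits) < 2:
        return None
    polished = polish_hits(sec_hits, len(consensus), config.max_gap_fill, rseq)
    region_id = f"{region.seq_id}:{region.start}-{region.end}"
    repeat_hits: List[RepeatHit] = []
    for h in polished:
        g_start = lo + h.start - 1
        g_end = lo + h.end - 1
        piece = seq[g_start - 1:g_end]
        oriented = piece if h.strand == "+" else reverse_complement(piece)
        repeat_hits.append(
            RepeatHit(
                seq_id=region.seq_id, start=g_start, end=g_end, strand=h.strand,
                sequence=oriented, region_id=region_id, family=family,
            )
        )
    covered = sum(h.end - h.start + 1 for h in polished)
    ann = RegionAnnotation(
        region=region, region_id=region_id, period=N, raw_period=est.N,
        consensus=consensus, family=family, hits=repeat_hits,
        coverage=covered / max(1, len(rseq)),
    )
    log.info(
        "region %s: period=%d consensus=%dbp hits=%d coverage=%.2f family=%s",
        region_id, N, len(consensus), len(repeat_hits), ann.coverage, family,
    )
    return ann


def _map_resolved(rseq: str, pattern: str, config: PipelineConfig):
    from .period import resolve_overlaps

    return resolve_overlaps(scan_pattern(rseq, pattern, config.max_mismatch_frac))


def annotate_sequence(
    seq_id: str,
    seq: str,
    config: PipelineConfig,
    templates: Optional[Sequence[TemplateFamily]] = None,
    aligner=None,
) -> Tuple[List, List[RegionAnnotation]]:
    """Annotate one sequence; returns (window scores, region annotations)."""
    if aligner is None:
        aligner = get_aligner(config.aligner)
    windows = compute_window_scores(seq, seq_id, config.window_size, config.k)
    scores = [w.score for w in windows]
    threshold = otsu_threshold(scores, config.otsu_bins) if len(scores) >= 2 else None
    regions = merge_repetitive_windows(windows, threshold, config.score_floor)
    pad = config.effective_region_pad
    queue = deque((r, True) for r in regions)  # (region, pad?)
    annotations: List[RegionAnnotation] = []
    budget = config.max_region_passes * max(1, len(regions))
    passes = 0
    while queue and passes < budget:
        region, use_pad = queue.popleft()
        passes += 1
        p = pad if use_pad else 0
        padded = (max(1, region.start - p), min(len(seq), region.end + p))
        ann = _annotate_region(seq, region, padded, config, templates, aligner)
        if ann is None:
            continue
        annotations.append(ann)
        # split on stretches of the *unpadded* region that mapping left bare
        rel = []
        for h in ann.hits:
            s = h.start - region.start + 1
            e = h.end - region.start + 1
            if e >= 1 and s <= region.width:
                rel.append(PatternHit(max(1, s), min(region.width, e), 0))
        min_unmapped = max(2 * ann.period, 100)
        for child in split_unmapped(region, rel, min_unmapped):
            queue.append((child, False))
    return windows, annotations


def _worker(args):
    seq_id, seq, config, templates = args
    return annotate_sequence(seq_id, seq, config, templates)


def run_pipeline(
    fasta,
    templates: Optional[Sequence[TemplateFamily]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full workflow.

    ``fasta`` is a path or a list of (seq_id, sequence) pairs.  Returns all
    tables in memory; use :func:`satkit.io.write_outputs` to persist them.
    When no repeats are found the tables are empty (not an error).
    """
    config = config or PipelineConfig()
    records = read_fasta(fasta) if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__") else list(fasta)
    if config.threads > 1 and len(records) > 1:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            results = list(
                pool.map(_worker, [(sid, s, config, templates) for sid, s in records])
            )
    else:
        results = [annotate_sequence(sid, s, config, templates) for sid, s in records]

    all_windows = []
    annotations: List[RegionAnnotation] = []
    for (windows, anns), (sid, _seq) in zip(results, records):
        all_windows.extend(windows)
        annotations.extend(anns)
    windows_df = pd.DataFrame(
        [{"seq_id": w.seq_id, "start": w.start, "end": w.end, "score": w.score}
         for w in all_windows],
        columns=["seq_id", "start", "end", "score"],
    )

    repeats: List[RepeatHit] = []
    aligner = get_aligner(config.aligner)
    # family groups: classified families genome-wide, de-novo families per region
    groups: Dict[str, List[RepeatHit]] = {}
    for ann in annotations:
        key = ann.family if ann.family is not None else ann.region_id
        groups.setdefault(key, []).extend(ann.hits)
        repeats.extend(ann.hits)
    family_consensus: Dict[str, str] = {}
    for key, hits in groups.items():
        seqs = [h.sequence for h in hits]
        consensus, dists = family_consensus_and_edits(
            seqs, aligner, msa_cap=min(config.consensus_max_hits * 2, config.max_msa_seqs)
        )
        family_consensus[key] = consensus
        for h, d in zip(hits, dists):
            h.edit_distance = d

    hor_rows: List[dict] = []
    hor_modal: Dict[Tuple[str, str], Optional[int]] = {}
    if config.hor_family is not None or config.hor_size_range is not None:
        params = HORParams(config.LM, config.VS_max)
        by_seq: Dict[str, List[RepeatHit]] = {}
        for h in repeats:
            if config.hor_family is not None:
                if h.family != config.hor_family:
                    continue
            else:
                lo, hi = config.hor_size_range
                if not (lo <= h.width <= hi):
                    continue
            by_seq.setdefault(h.seq_id, []).append(h)
        fam_label = config.hor_family or "size_class"
        for sid in sorted(by_seq):
            monomers = sorted(by_seq[sid], key=lambda h: h.start)
            if len(monomers) < 2:
                continue
            hors, _matrix = find_hors(
                [m.sequence for m in monomers],
                [m.strand for m in monomers],
                params, aligner, family=fam_label, chunk_cap=config.max_msa_seqs,
            )
            rep = repetitiveness_scores(hors, len(monomers))
            for m, r in zip(monomers, rep):
                m.repetitiveness = r
            _proxy, modal = hor_period_proxy(hors, len(monomers))
            hor_modal[(sid, fam_label)] = modal
            for h in hors:
                b1s, b1e = h.block1_range
                b2s, b2e = h.block2_range
                hor_rows.append({
                    "seq_id": sid, "family": fam_label, "orientation": h.orientation,
                    "block1_start_idx": b1s, "block1_end_idx": b1e,
                    "block2_start_idx": b2s, "block2_end_idx": b2e,
                    "block1_bp_start": monomers[b1s - 1].start,
                    "block1_bp_end": monomers[b1e - 1].end,
                    "block2_bp_start": monomers[b2s - 1].start,
                    "block2_bp_end": monomers[b2e - 1].end,
                    "length": h.length, "period": h.period, "total_VS": h.total_VS,
                })

    repeats_sorted = sorted(repeats, key=lambda h: (h.seq_id, h.start, h.end))
    repeats_df = pd.DataFrame(
        [{
            "seq_id": h.seq_id, "start": h.start, "end": h.end, "width": h.width,
            "strand": h.strand, "region_id": h.region_id, "family": h.family,
            "edit_distance": h.edit_distance, "repetitiveness": h.repetitiveness,
            "sequence": h.sequence,
        } for h in repeats_sorted],
        columns=REPEAT_COLUMNS,
    )
    regions_df = pd.DataFrame(
        [{
            "seq_id": a.region.seq_id, "start": a.region.start, "end": a.region.end,
            "source_windows": a.region.source_windows, "period": a.period,
            "family": a.family, "n_repeats": len(a.hits), "consensus": a.consensus,
        } for a in sorted(annotations, key=lambda a: (a.region.seq_id, a.region.start))],
        columns=REGION_COLUMNS,
    )
    hors_df = None
    if config.hor_family is not None or config.hor_size_range is not None:
        hors_df = pd.DataFrame(hor_rows, columns=HOR_COLUMNS)
    return PipelineResult(
        repeats=repeats_df, regions=regions_df, windows=windows_df, hors=hors_df,
        family_consensus=family_consensus, hor_period_modal=hor_modal,
    )
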