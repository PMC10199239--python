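# Methods

## Problem and model

Satellite DNA occupies large genomic regions as tandem arrays of a unit
repeat (the *monomer*, typically ~100–200 bp in centromeres but anywhere
from telomeric 7-mers to kilobase units). satkit annotates such arrays in
any nucleotide assembly with no prior knowledge of the monomer: it locates
repetitive regions, estimates the monomer period, derives a consensus,
maps every monomer copy with coordinates and strand, optionally assigns
copies to named families, and reports higher-order repeats (HORs) —
duplications of multi-monomer blocks.

The working assumptions are those of tandem-array biology: arrays are
*continuous* runs of *highly similar* copies of *similar unit size*.
Interspersed repeats and transposable elements are out of scope by design,
and repeats interrupted by short unrelated inserts may be concatenated
with the inserts into larger units.

## Pipeline

1. **Window scoring.** Each sequence is tiled with non-overlapping
   windows (1500 bp). A window's repeat-content score is the fraction of
   positions whose k-mer (k = 10) occurs at least twice in the window.
   Unique sequence scores near 0; tandem arrays score 0.8–1.0 (the
   trailing k−1 positions start no k-mer, and each point mutation makes
   ~k k-mers unique). The score distribution over a genome is strongly
   bimodal.
2. **Otsu thresholding.** The threshold separating the two modes is
   found with Otsu's between-class-variance criterion on a 256-bin
   histogram of the scores. Windows at or above
   max(threshold, floor = 0.5) are repetitive; adjacent repetitive
   windows merge into regions. The absolute floor matters in two edge
   cases: a repeat-free input, where the "optimal" split of a unimodal
   near-zero distribution would otherwise call background repetitive, and
   a degenerate all-equal distribution, where Otsu has no split at all
   (the thresholder then returns a "no split" sentinel).
3. **Period estimate.** Within a region, distances between *consecutive*
   occurrences of identical k-mers are tallied (consecutive, not all
   pairs: same mode on tandem text, O(L) memory). The modal distance N in
   [4, 1000] bp is the period estimate; ties break toward the smaller
   distance. Regions whose mode count is below `min_period_support` (5)
   are treated as repeat-free — one or two coincidental k-mer pairs in
   otherwise unique sequence must not seed an annotation.
4. **Period splitting.** Higher-order structure can put the k-mer mode at
   a multiple of the true monomer (variant monomers repeat exactly only
   across blocks). A divisor scan (d = 2..12) sums histogram mass within
   ±max(2, 2% of N/d) of round(N/d); d qualifies when that mass reaches a
   configurable percentage of the mode count, composite d additionally
   require all proper divisors to qualify, and the largest qualifying d
   wins. At the default threshold of 100% the scan practically never
   fires; 5% is the setting used for HOR-rich arrays.
5. **Candidate sampling and primary consensus.** Six random N-length
   substrings of the region are mapped back with a fixed-length Hamming
   matcher (budget 20% of the pattern length, no indels; overlaps
   resolved greedily left-to-right, fewer mismatches first). The
   best-covering candidate's hits are multiply aligned and a per-column
   majority (gap-majority columns dropped, base ties broken A<C<G<T)
   gives the primary consensus.
6. **Frame canonicalization.** A monomer is a circular string; to give
   related monomers one reading frame, every rotation of the consensus
   and of its reverse complement is scored with S = Σ_j j·K_j, where K is
   the positional hexamer hash Σ_i V_i·4^i (A=0, C=1, T=2, G=3,
   i = 1..6) over the circular 6-mers in order, and the rotation with
   minimal S wins (ties: forward strand, smallest offset). The scores of
   all n rotations follow from the exact integer recurrence
   S(r+1) = S(r) − ΣK + n·K[r], so canonicalization is O(n).
7. **Family classification (optional).** Against user templates
   (name + consensus), similarity is the Jaccard index of circular 8-mer
   sets, taken as the max over the query's two strands (the canonical
   frame lands on an arbitrary strand). Significance at level α = 0.05
   compares the best-template score with the empirical 95th percentile of
   the same statistic for 100 character-shuffles of the query. Classified
   consensuses are re-rotated to the template frame by exhaustive
   rotation/strand alignment (global, +1/−1/−2).
8. **Secondary mapping and polishing.** The final consensus and its
   reverse complement are mapped jointly across the region; each hit's
   strand records which orientation matched. Between adjacent hits,
   overlaps shorter than half the consensus are split evenly (extra base
   upstream), longer overlaps drop the shorter hit (ties drop the
   downstream one), and gaps of 1–4 bp are closed evenly. The polishing
   sweep backtracks after every edit, so it converges and is idempotent
   even on pathological (nested) input.
9. **Region splitting.** Unmapped stretches longer than
   max(2N, 100) bp re-enter the pipeline as fresh regions, which resolves
   adjacent arrays of distinct families. Initial window-derived regions
   are padded by one window on each side before mapping — window tiling
   quantizes array edges to 1500 bp and the padding lets the matcher
   recover monomers in the truncated edge windows, while unique padding
   sequence yields no hits. Split-off regions are not padded (their edges
   are exact).
10. **Edit distances.** Classified repeats are aligned per family
    (de-novo repeats per region), a family consensus is called with the
    same majority rule, and every monomer gets a Levenshtein edit
    distance to it (computed with edlib).
11. **HOR detection.** Same-family monomers of a sequence are multiply
    aligned; every monomer pair's *variant score* (VS) counts alignment
    columns where the rows differ (gap-vs-base counts, gap-vs-gap does
    not). Runs along diagonal offset d of the VS matrix — consecutive
    pairs (i, i+d) with VS ≤ VS_max — of at least LM pairs are direct
    HORs with period d; runs along anti-diagonals — pairs (i, j),
    (i+1, j−1), … restricted to opposite-strand monomers — are inverted
    HORs. One HOR is reported per maximal run; monomers may belong to
    several HORs and the two blocks of one HOR may overlap when
    d < length. Per monomer, *repetitiveness* sums the lengths of all its
    HORs and the *period proxy* is the smallest block distance among its
    direct HORs; the per-array mode of the proxy estimates the HOR
    period.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` | 1500 bp | repeat-content window |
| `k` | 10 | k-mer for scoring and period estimate |
| `n_samples` | 6 | monomer candidates per region |
| `min_monomer`/`max_monomer` | 4 / 1000 bp | admissible period range |
| `max_mismatch_frac` | 0.2 | Hamming budget of the matcher |
| `max_gap_fill` | 4 bp | largest polished gap |
| `N_max_div_threshold_pct` | 100 (off) | period-splitting threshold |
| `max_N_split` | 12 | largest divisor tried |
| `LM` / `VS_max` | 3 / 5 | HOR run length / per-pair score caps |
| `n_perm` / `alpha` | 100 / 0.05 | classification permutation test |
| `score_floor` | 0.5 | absolute repetitive-window floor |
| `min_period_support` | 5 | minimal k-mer mode count per region |
| `max_msa_seqs` | 20000 | family-MSA chunking cap |

`min_monomer`/`max_monomer` span telomeric 7-mers to kilobase satellites;
the 20% mismatch budget admits diverged monomers while keeping hits
monomer-length; `min_period_support` and the padding behaviour are
engineering additions explained above.

## Alignment engines

The default engine is a deterministic center-star progressive aligner:
the center sequence (minimal summed edit distance, edlib) is aligned
pairwise to every other sequence with global Needleman–Wunsch
(+1/−1/−2, Bio.Align's C implementation) and merged on center
coordinates. For near-identical same-length monomer families this is
essentially exact and fully reproducible. An external MAFFT engine
(`aligner="external"`) is available for large or gappy families.
Family sets larger than `max_msa_seqs` are processed in overlapping
chunks with deduplication; inputs at or under the cap take the single-MSA
path, so chunking cannot change their results, while over the cap HORs
spanning further than the chunk overlap are not recoverable.

## Determinism

All random draws (candidate sampling, permutation shuffles) derive from
per-region streams seeded by (master seed, crc32(seq_id), region start),
so results are independent of execution order: serial and multi-process
runs are byte-identical, as are repeated runs with one seed.

## Synthetic fixtures: what they do and do not show

The generator emulates the *structure* the method assumes: uniform random
monomers, tandem copies with independent per-base substitutions and
length-capped single-base indels (copy length within ±5% of the monomer),
HOR arrays built as blocks of distinct monomer variants duplicated with
fresh low-rate mutations (reverse-complemented for inverted fixtures),
and unique background rejection-sampled against accidental window-level
periodicity. It does not model satellite evolution (unequal crossover,
library homogenization), GC bias, nested insertions of transposable
elements, or assembly artefacts. Passing recovery tests therefore shows
the algorithms are correct under the method's own assumptions, not that
real centromeres meet those assumptions.

Test-suite study conditions (chosen for desk-scale runtimes): recovery
arrays with monomer lengths {7, 50, 178, 500} bp at copy numbers
{300, 60, 40, 50} and 1% substitution divergence inside 5 kb unique
flanks — array lengths are chosen so the partial monomer copies at array
edges, which a fixed-length matcher cannot annotate, stay well under the
5% recall budget. HOR fixtures use a 178 bp monomer, 4 blocks, periods
{3, 5, 12}, 6% within-block and 0.3% between-block divergence, analysed
with the 5% period-splitting threshold and the 160–180 bp monomer size
class; the inverted-orientation fixture lowers within-block divergence to
3% because its windows contain no same-strand same-variant k-mer pairs
and would otherwise score below the repeat floor.

## Numerical and tie-break choices

Window scores use the window length as denominator (short final windows
their own length); k-mers containing non-ACGT characters never count as
repeated, and candidate monomers containing them are redrawn. Otsu uses
256 equal-width bins on [0, 1], reports the lower edge of the first
upper-class bin, and takes the first maximum (lowest threshold) on ties.
Overlap resolution prefers fewer mismatches, then the leftmost hit.
Equal-score rotations prefer the forward strand, then the smallest
offset. Polishing gives the extra base of odd overlaps/gaps to the
upstream hit and treats an overlap of exactly half the consensus as long
(removal branch). Consensus columns tied between a gap and a base keep
the base.

## Known limitations

* Only continuous tandem arrays are annotated; isolated or interspersed
  repeat copies are invisible.
* Fixed-length matching cannot annotate the partial monomer copies at
  array edges, and arrays whose copies drift far beyond the 20% mismatch
  budget fragment into multiple regions.
* De-novo family labels are per-region; cross-region family unification
  requires templates (or the monomer-size window used for HOR analysis).
* HOR detection requires the family's monomers to be mutually
  distinguishable (pairwise VS above VS_max between different variants);
  homogeneous arrays report dense trivial HORs at every offset, and the
  period proxy is then the minimal offset, not a biological period.
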