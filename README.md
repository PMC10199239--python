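# satkit

De-novo annotation of tandem repeat arrays, satellite families and
higher-order repeats (HORs) in nucleotide assemblies.

Complete long-read assemblies now include the megabase satellite arrays
of centromeres, which need annotation at the level of the individual
repeat unit: where each monomer copy sits, on which strand, in which
family, and how monomers group into higher-order block duplications.
satkit does this from a FASTA file alone, with no prior knowledge of
monomer sequences.

## Method in brief

* **Region finding** — windows (1500 bp) are scored by the proportion of
  non-unique 10-mers; Otsu's threshold separates the bimodal score
  distribution and adjacent repetitive windows merge into regions.
* **Period and consensus** — the monomer period N is the modal distance
  between identical k-mers; random N-length samples are mapped back
  (Hamming matcher, 20% budget) and the best-covering sample's hits are
  aligned into a majority consensus. An optional divisor scan splits
  periods that are multiples of the true monomer.
* **Frame canonicalization** — each rotation (both strands) of the
  consensus is scored with S = Σ_j j·K_j over its circular 6-mers, where
  K = Σ_i V_i·4^i (A=0, C=1, T=2, G=3); the minimal-S rotation is the
  canonical frame, so related monomers always align without end gaps.
* **Classification** — consensuses are compared to user templates by the
  Jaccard index of circular 8-mer sets with a permutation significance
  test, then re-rotated into the template frame.
* **Refinement** — the consensus is re-mapped on both strands, overlaps
  and small gaps between neighbouring monomers are polished, and every
  monomer gets a Levenshtein edit distance to its family consensus.
* **HOR detection** — from the family alignment, each monomer pair's
  variant score VS counts differing columns; runs of pairs with
  VS ≤ VS_max (default 5) of at least LM (default 3) pairs along matrix
  diagonals are direct HORs, along anti-diagonals (opposite strands)
  inverted HORs.

See `docs/methods.md` for the full procedure, parameters and limitations.

## Worked example

```python
from satkit import (ArraySpec, GenomeSpec, PipelineConfig,
                    generate_genome_fixture, run_pipeline)

spec = GenomeSpec("chr1",
                  arrays=(ArraySpec(monomer_length=178, n_copies=40,
                                    sub_rate=0.01),),
                  flank=5000)
fixture = generate_genome_fixture(spec, seed=1)
result = run_pipeline(fixture.records, templates=None,
                      config=PipelineConfig(seed=1))
print(result.regions[["seq_id", "start", "end", "period", "n_repeats"]])
```

prints

```
  seq_id  start    end  period  n_repeats
0   chr1   4501  12000     178         39
```

one repetitive region whose monomer period was estimated at 178 bp from
identical-k-mer spacings, with 39 annotated monomer copies
(`result.repeats` holds one row per copy: coordinates, strand, sequence,
family and edit distance). The scripts under `examples/` walk through
de-novo annotation, template classification, HOR analysis and fixture
generation, each printing the numbers it computes.

A thin CLI wraps the same pipeline:

```sh
satkit run genome.fa --seqt templates.csv --horclass cen178 --out out/
satkit fixtures --monomer-length 178 --n-copies 50 --out fixture/
```

writing repeats/regions/HOR tables as CSV plus GFF3, BED, bedGraph and
overview plots.

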