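"""Pipeline configuration.

All tunables of the annotation workflow live in a single frozen dataclass so a
run is fully described by (input, templates, config).  Defaults follow the
method's published settings where one exists; the remaining knobs are
engineering parameters documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the tandem-repeat annotation pipeline.

    Parameters
    ----------
    window_size:
        Width (bp) of the non-overlapping windows scored for repeat content.
    k:
        k-mer length used both for window scoring and for the
        identical-k-mer-distance period estimate.
    n_samples:
        Number of random monomer-length candidates sampled per region.
    min_monomer, max_monomer:
        Admissible monomer period range (bp).
    max_mismatch_frac:
        Hamming mismatch budget of the fixed-length monomer matcher, as a
        fraction of the pattern length.
    max_gap_fill:
        Largest inter-monomer gap (bp) closed by the polishing step.
    N_max_div_threshold_pct:
        Percentage threshold for splitting a multi-monomer period into its
        base monomer (100 disables splitting).
    max_N_split:
        Largest integer divisor tried when splitting the period.
    LM, VS_max:
        Higher-order-repeat parameters: minimal monomer pairs per HOR block
        and maximal per-pair variant score.
    n_perm, alpha:
        Permutation count and significance level of the family-classification
        test.
    score_floor:
        Absolute repeat-content floor a window must reach to count as
        repetitive, applied on top of (or instead of, in degenerate cases)
        the Otsu threshold.
    seed:
        Master seed; all per-region random streams derive from it.
    threads:
        Number of worker processes (sequences are independent).
    aligner:
        ``"internal"`` (built-in center-star progressive aligner) or
        ``"external"`` (MAFFT subprocess).
    outdir:
        Output directory for tables/plots; ``None`` keeps results in memory.
    """

    window_size: int = 1500
    k: int = 10
    n_samples: int = 6
    min_monomer: int = 4
    max_monomer: int = 1000
    max_mismatch_frac: float = 0.2
    max_gap_fill: int = 4
    N_max_div_threshold_pct: float = 100.0
    max_N_split: int = 12
    LM: int = 3
    VS_max: int = 5
    n_perm: int = 100
    alpha: float = 0.05
    score_floor: float = 0.5
    seed: int = 0
    threads: int = 1
    aligner: str = "internal"
    outdir: Optional[str] = None

    # Engineering parameters (see docs/methods.md).
    otsu_bins: int = 256
    region_pad: Optional[int] = None  # None -> one window_size on each side
    min_period_support: int = 5
    consensus_max_hits: int = 100
    max_msa_seqs: int = 20000
    hor_family: Optional[str] = None
    hor_size_range: Optional[Tuple[int, int]] = None
    max_region_passes: int = 30
    debug: bool = False

    def __post_init__(self) -> None:
        for name in (
            "window_size", "k", "n_samples", "min_monomer", "max_monomer",
            "max_gap_fill", "max_N_split", "LM", "VS_max", "n_perm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.max_mismatch_frac <= 1:
            raise ValueError("max_mismatch_frac must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_monomer > self.max_monomer:
            raise ValueError("min_monomer exceeds max_monomer")
        if self.aligner not in ("internal", "external"):
            raise ValueError("aligner must be 'internal' or 'external'")

    @property
    def effective_region_pad(self) -> int:
        return self.window_size if self.region_pad is None else self.region_pad

    def with_(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
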