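"""Overview plots: circular family summary, linear repeat tracks, HOR dot plot.

Simplified renderings meant for a first look at an annotation; plotting
failures are logged and never abort a run.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

log = logging.getLogger("satkit")


def plot_linear(repeats: pd.DataFrame, outdir: Path) -> Optional[Path]:
    """Per-sequence track of repeat positions vs monomer size."""
    if repeats.empty:
        log.info("linear plot skipped: no repeats")
        return None
    seq_ids = sorted(repeats["seq_id"].unique())
    fig, axes = plt.subplots(len(seq_ids), 1, figsize=(10, 2.2 * len(seq_ids)),
                             squeeze=False)
    for ax, sid in zip(axes[:, 0], seq_ids):
        sub = repeats[repeats["seq_id"] == sid]
        colors = np.where(sub["strand"] == "+", "tab:red", "tab:blue")
        ax.vlines(sub["start"], 0, sub["width"], colors=colors, lw=0.8)
        ax.set_title(sid, fontsize=9)
        ax.set_ylabel("monomer bp")
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    path = outdir / "repeats_linear.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_circular(repeats: pd.DataFrame, seq_lengths: Dict[str, int],
                  outdir: Path) -> Optional[Path]:
    """Circular overview: one ring per sequence, arcs where repeats lie,
    shaded by monomer length."""
    if repeats.empty:
        log.info("circular plot skipped: no repeats")
        return None
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="polar")
    seq_ids = sorted(seq_lengths)
    cmap = plt.get_cmap("viridis")
    wmax = max(1, repeats["width"].max())
    for ring, sid in enumerate(seq_ids):
        L = seq_lengths[sid]
        sub = repeats[repeats["seq_id"] == sid]
        for _, row in sub.iterrows():
            theta = np.linspace(2 * np.pi * (row["start"] - 1) / L,
                                2 * np.pi * row["end"] / L, 8)
            ax.plot(theta, np.full_like(theta, 1.0 + ring),
                    color=cmap(row["width"] / wmax), lw=4, solid_capstyle="butt")
    ax.set_yticks([1.0 + r for r in range(len(seq_ids))])
    ax.set_yticklabels(seq_ids, fontsize=7)
    ax.set_xticks([])
    path = outdir / "repeats_circos.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_hor_dot(hors: pd.DataFrame, outdir: Optional[Path] = None, ax=None):
    """Dot plot of HOR block start positions, shaded by mean per-pair VS.

    With an explicit ``ax`` the plot is drawn there and the axes returned
    (no file written); otherwise a PNG is saved under ``outdir``.
    """
    if hors is None or hors.empty:
        log.info("HOR dot plot skipped: no HORs")
        return None
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 6))
    mean_vs = hors["total_VS"] / hors["length"]
    sc = ax.scatter(hors["block1_bp_start"], hors["block2_bp_start"],
                    c=mean_vs, cmap="magma_r", s=12)
    ax.set_xlabel("block 1 start (bp)")
    ax.set_ylabel("block 2 start (bp)")
    if not own_fig:
        return ax
    fig.colorbar(sc, label="mean VS per pair")
    fig.tight_layout()
    path = Path(outdir) / "hor_dotplot.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_plots(result, seq_lengths: Dict[str, int], outdir) -> Dict[str, Path]:
    """Generate all plots; failures are logged, never fatal."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}
    for name, fn, args in (
        ("linear", plot_linear, (result.repeats, outdir)),
        ("circular", plot_circular, (result.repeats, seq_lengths, outdir)),
        ("hor_dot", plot_hor_dot, (result.hors, outdir)),
    ):
        try:
            p = fn(*args)
            if p is not None:
                out[name] = p
        except Exception:  # pragma: no cover - defensive
            log.exception("plot %s failed", name)
    return out
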