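"""Readers and writers for all external formats.

Coordinates are 1-based inclusive in memory and in CSV/GFF3 output; BED and
bedGraph exports convert to 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .shifting import TemplateFamily

REPEAT_COLUMNS = [
    "seq_id", "start", "end", "width", "strand", "region_id",
    "family", "edit_distance", "repetitiveness", "sequence",
]
REGION_COLUMNS = [
    "seq_id", "start", "end", "source_windows", "period",
    "family", "n_repeats", "consensus",
]
HOR_COLUMNS = [
    "seq_id", "family", "orientation",
    "block1_start_idx", "block1_end_idx", "block2_start_idx", "block2_end_idx",
    "block1_bp_start", "block1_bp_end", "block2_bp_start", "block2_bp_end",
    "length", "period", "total_VS",
]


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a (possibly gzip-compressed) FASTA file.

    Returns (id, sequence) in file order; sequences are uppercased and the
    id is the first whitespace-delimited token of the header.  Records with
    empty ids or sequences are rejected by name.
    """
    out: List[Tuple[str, str]] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise ValueError(f"malformed FASTA: record {len(out) + 1} has no id")
            if not seq:
                raise ValueError(f"malformed FASTA: record {rec.id!r} has empty sequence")
            out.append((rec.id, seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def read_templates_csv(path) -> List[TemplateFamily]:
    """Template table: CSV with header ``name,sequence``."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "name" not in cols or "sequence" not in cols:
        raise ValueError("template CSV must have columns 'name' and 'sequence'")
    templates = [
        TemplateFamily(str(row[cols["name"]]), str(row[cols["sequence"]]))
        for _, row in df.iterrows()
    ]
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("template names must be unique")
    return templates


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_repeats_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"family": "object"})


def write_gff3(repeats: pd.DataFrame, path) -> None:
    """Repeats as GFF3 ``tandem_repeat`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in repeats.iterrows():
            family = row["family"] if pd.notna(row["family"]) else "de_novo"
            attrs = f"ID=repeat{i};family={family};region={row['region_id']}"
            if pd.notna(row.get("edit_distance")):
                attrs += f";edit_distance={int(row['edit_distance'])}"
            fh.write(
                f"{row['seq_id']}\tsatkit\ttandem_repeat\t{int(row['start'])}\t"
                f"{int(row['end'])}\t.\t{row['strand']}\t.\t{attrs}\n"
            )


def read_gff3_intervals(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({"seq_id": f[0], "start": int(f[3]),
                         "end": int(f[4]), "strand": f[6]})
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand"])


def write_bed(repeats: pd.DataFrame, path) -> None:
    """Repeats as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in repeats.iterrows():
            family = row["family"] if pd.notna(row["family"]) else "de_novo"
            fh.write(
                f"{row['seq_id']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{family}\t0\t{row['strand']}\n"
            )


def read_bed_intervals(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append({"seq_id": f[0], "start": int(f[1]) + 1,
                         "end": int(f[2]), "strand": f[5] if len(f) > 5 else "+"})
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand"])


def write_bedgraph(windows: pd.DataFrame, path) -> None:
    """Window repeat-content scores as bedGraph for genome-browser inspection."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="repeat_content_score"\n')
        for _, row in windows.iterrows():
            fh.write(
                f"{row['seq_id']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{row['score']:.6f}\n"
            )


def write_outputs(result, outdir) -> dict:
    """Write all pipeline tables (CSV, GFF3, BED, bedGraph) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["repeats_csv"] = outdir / "repeats.csv"
    write_csv(result.repeats, paths["repeats_csv"])
    paths["regions_csv"] = outdir / "regions.csv"
    write_csv(result.regions, paths["regions_csv"])
    if result.hors is not None:
        paths["hors_csv"] = outdir / "hors.csv"
        write_csv(result.hors, paths["hors_csv"])
    paths["gff3"] = outdir / "repeats.gff3"
    write_gff3(result.repeats, paths["gff3"])
    paths["bed"] = outdir / "repeats.bed"
    write_bed(result.repeats, paths["bed"])
    paths["bedgraph"] = outdir / "window_scores.bedgraph"
    write_bedgraph(result.windows, paths["bedgraph"])
    return paths
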