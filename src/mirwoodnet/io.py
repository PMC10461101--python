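"""File-format adapters: FASTA/FASTQ via Biopython, GFF3/BED via pandas.

Coordinates are 1-based inclusive internally; BED input is converted from
0-based half-open on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = ["read_fasta", "read_fastq", "read_gff3", "read_bed", "read_expression"]


def read_fasta(path: str | Path, unique: bool = True) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if unique and rec.id in records:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def read_fastq(path: str | Path) -> list[tuple[str, list[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Feature table with columns chrom, source, type, start, end, strand, attr."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attr"],
        dtype={"chrom": str},
    )
    if (df["end"] < df["start"]).any():
        bad = df[df["end"] < df["start"]].iloc[0]
        raise ValueError(f"malformed GFF3 interval: {bad['chrom']}:{bad['start']}-{bad['end']}")
    return df[["chrom", "source", "type", "start", "end", "strand", "attr"]]


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open) converted to 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "type"][: df.shape[1]]
    if "type" not in df.columns:
        df["type"] = "region"
    if (df["end"] < df["start"]).any():
        raise ValueError("malformed BED interval: end < start")
    df["start"] = df["start"] + 1  # to 1-based inclusive
    return df[["chrom", "start", "end", "type"]]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with a gene_id index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene IDs in expression matrix")
    return df
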