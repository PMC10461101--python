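"""Small-RNA read cleaning, tag collapsing, exact mapping and profiling.

Cleaning follows the study's filters: 3' adapter removal, then discarding
reads shorter than 18 nt, reads with more than 10% N bases, and reads whose
3' end is low quality (any of the last ``tail_window`` bases with Q < 20,
where Q = -10*log10 of the base-call error probability). Clean reads in the
18-30 nt window ("total sRNA") are collapsed to unique tags and placed on
the genome by exact matching on both strands; tags from annotated non-miRNA
classes (rRNA, tRNA, snRNA, snoRNA, repeats, protein-coding genes) are then
masked out by coordinate overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import revcomp_dna

__all__ = [
    "ReadSet",
    "CleanStats",
    "TagCatalog",
    "phred_q",
    "clean_reads",
    "collapse_and_map",
    "mask_annotated",
    "length_profile",
    "first_base_profile",
    "MASKED_FEATURE_TYPES",
]

MASKED_FEATURE_TYPES = {"rRNA", "tRNA", "snRNA", "snoRNA", "repeat_region", "gene", "mRNA", "region"}


@dataclass
class ReadSet:
    sample_id: str
    reads: list[tuple[str, list[int]]]  # (sequence, phred qualities)

    def __post_init__(self) -> None:
        for seq, qual in self.reads[:100]:  # spot-check invariants cheaply
            if len(seq) != len(qual):
                raise ValueError(f"{self.sample_id}: sequence/quality length mismatch")


@dataclass
class CleanStats:
    sample_id: str
    raw_reads: int
    clean_reads: int
    total_srna: int
    mapped_srna: int = 0
    mapping_ratio: float = 0.0

    def compute_ratio(self) -> None:
        self.mapping_ratio = (
            round(self.mapped_srna / self.total_srna * 100, 2) if self.total_srna else 0.0
        )


def phred_q(error_ratio: float) -> float:
    """Phred quality Q = -10*log10(error probability)."""
    if not 0 < error_ratio <= 1:
        raise ValueError(f"error_ratio must be in (0, 1], got {error_ratio}")
    return -10.0 * math.log10(error_ratio)


def _trim_adapter(seq: str, qual: list[int], probe: str) -> tuple[str, list[int]]:
    i = seq.find(probe)
    if i >= 0:
        return seq[:i], qual[:i]
    return seq, qual


def clean_reads(
    raw: ReadSet,
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    max_n_frac: float = 0.10,
    min_tail_q: int = 20,
    tail_window: int = 3,
    min_adapter_match: int = 8,
) -> tuple[ReadSet, CleanStats]:
    """Adapter-trim and filter one sample's reads.

    Returns the retained sRNA-sized reads (min_len..max_len) and the
    per-sample accounting: ``clean_reads`` counts everything that survives
    the quality filters at >= min_len; ``total_srna`` is the subset within
    the sRNA length window that downstream stages use.
    """
    if not raw.reads:
        raise ValueError(f"{raw.sample_id}: empty read set")
    if set(adapter) - set("ACGT") or len(adapter) < min_adapter_match:
        raise ValueError("adapter must be a DNA string of at least the match length")
    probe = adapter[:min_adapter_match]
    kept: list[tuple[str, list[int]]] = []
    n_clean = 0
    for seq, qual in raw.reads:
        seq, qual = _trim_adapter(seq, qual, probe)
        if len(seq) < min_len:
            continue
        if seq.count("N") / len(seq) > max_n_frac:
            continue
        if any(q < min_tail_q for q in qual[-tail_window:]):
            continue
        n_clean += 1
        if len(seq) <= max_len:
            kept.append((seq, qual))
    stats = CleanStats(
        sample_id=raw.sample_id,
        raw_reads=len(raw.reads),
        clean_reads=n_clean,
        total_srna=len(kept),
    )
    return ReadSet(sample_id=raw.sample_id, reads=kept), stats


@dataclass
class TagCatalog:
    """Unique tags with per-sample read counts and exact-match genome loci."""

    counts: pd.DataFrame  # index tag sequence (DNA), columns samples
    loci: dict[str, list[tuple[str, int, str]]]  # tag -> (chrom, 1-based start, strand)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def mapped_tags(self) -> list[str]:
        return [t for t in self.counts.index if self.loci.get(t)]

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def collapse_and_map(
    clean: dict[str, ReadSet], genome: dict[str, str]
) -> tuple[TagCatalog, dict[str, int]]:
    """Collapse clean reads to unique tags and exact-match them to the genome.

    Returns the catalog and the per-sample mapped read counts (reads whose
    tag has at least one locus). A tag's count is per read, assigned once
    regardless of how many loci it matches.
    """
    if not genome or not any(genome.values()):
        raise ValueError("empty genome")
    samples = list(clean)
    tag_counts: dict[str, dict[str, int]] = {}
    for sample, rs in clean.items():
        for seq, _ in rs.reads:
            d = tag_counts.setdefault(seq, dict.fromkeys(samples, 0))
            d[sample] += 1
    tags = sorted(tag_counts)
    counts = pd.DataFrame(
        [[tag_counts[t][s] for s in samples] for t in tags], index=tags, columns=samples
    )
    counts.index.name = "tag"
    loci: dict[str, list[tuple[str, int, str]]] = {}
    for t in tags:
        placements = []
        rc = revcomp_dna(t)
        for chrom in sorted(genome):
            seq = genome[chrom]
            for i in _find_all(seq, t):
                placements.append((chrom, i + 1, "+"))
            for i in _find_all(seq, rc):
                placements.append((chrom, i + 1, "-"))
        loci[t] = placements
    catalog = TagCatalog(counts=counts, loci=loci)
    mapped = {
        s: int(counts.loc[[t for t in tags if loci[t]], s].sum()) if tags else 0 for s in samples
    }
    return catalog, mapped


def mask_annotated(catalog: TagCatalog, mask: pd.DataFrame) -> TagCatalog:
    """Drop tags whose every locus overlaps a masked feature.

    ``mask`` needs columns chrom/start/end (1-based inclusive); tags with at
    least one unmasked locus are retained, and unmapped tags are untouched
    (they were never attributed to an annotated class).
    """
    if (mask["end"] < mask["start"]).any():
        raise ValueError("malformed mask interval: end < start")
    trees: dict[str, IntervalTree] = {}
    for r in mask.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)
    keep = []
    for t in catalog.tags:
        placements = catalog.loci[t]
        if not placements:
            keep.append(t)
            continue
        unmasked = False
        for chrom, start, _ in placements:
            tree = trees.get(chrom)
            if tree is None or not tree.overlap(start, start + len(t)):
                unmasked = True
                break
        if unmasked:
            keep.append(t)
    return TagCatalog(
        counts=catalog.counts.loc[keep].copy(), loci={t: catalog.loci[t] for t in keep}
    )


def length_profile(catalog: TagCatalog, min_len: int = 18, max_len: int = 30) -> pd.Series:
    """Read-weighted fraction of tags at each length in [min_len, max_len]."""
    if catalog.counts.empty:
        raise ValueError("empty catalog")
    totals = catalog.total_counts()
    lengths = totals.index.str.len()
    out = pd.Series(0.0, index=range(min_len, max_len + 1), name="fraction")
    grp = totals.groupby(lengths).sum()
    for ln, v in grp.items():
        if min_len <= ln <= max_len:
            out.loc[ln] = v
    total = out.sum()
    if total == 0:
        raise ValueError("no tags within the length window")
    return out / total


def first_base_profile(catalog: TagCatalog, min_len: int = 18, max_len: int = 30) -> pd.DataFrame:
    """Length x base matrix of first-nucleotide fractions (RNA alphabet).

    Rows with no tags at that length are all-zero; populated rows sum to 1.
    """
    if catalog.counts.empty:
        raise ValueError("empty catalog")
    totals = catalog.total_counts()
    mat = pd.DataFrame(0.0, index=range(min_len, max_len + 1), columns=list("AUGC"))
    for tag, n in totals.items():
        ln = len(tag)
        if min_len <= ln <= max_len:
            base = "U" if tag[0] == "T" else tag[0]
            if base in mat.columns:
                mat.loc[ln, base] += n
    sums = mat.sum(axis=1)
    nz = sums > 0
    mat.loc[nz] = mat.loc[nz].div(sums[nz], axis=0)
    return mat
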