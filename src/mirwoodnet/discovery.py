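"""Known-miRNA assignment, novel-miRNA calling and family assignment.

A tag is a *known* miRNA when it matches a reference mature sequence exactly
or with at most two bases trimmed/extended at the termini (no internal
mismatch). Remaining mapped tags become *novel* candidates: the genomic
window around each locus is folded by base-pair maximization and accepted as
a pre-miRNA hairpin when

  (i)   the mature duplex is near-complete: at least max(14, len-3) mature
        bases are paired,
  (ii)  at least 60% of mature bases are paired,
  (iii) G:U wobbles make up at most 25% of the mature pairs (pair
        maximization over random sequence leans heavily on wobbles;
        genuine precursor stems do not),
  (iv)  all partners of mature bases lie on one side of the mature span
        (the mature coincides with one stem arm), and
  (v)   the mature-arm stem closes a single terminal loop (at most two
        incidental pairs inside the innermost mature pair; more means a
        branched path).

Because pair maximization over a long random flank can bury the true stem,
each of the two canonical windows (downstream- and upstream-extended) is tried
at graded extents up to the full flank; a candidate is accepted if any
extent passes. Novel IDs are assigned in genome coordinate order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

from ._seq import WATSON_CRICK, revcomp_dna, to_dna, to_rna
from .fold import fold_nussinov, pair_table
from .reads import TagCatalog

__all__ = [
    "MirnaRecord",
    "HairpinCandidate",
    "match_known",
    "call_novel",
    "assign_family",
    "tissue_mirna_sets",
]

_FAMILY_RE = re.compile(r"(mir|miR|MIR)[-]?(\d+)")


@dataclass
class HairpinCandidate:
    window_seq: str  # RNA, 5'->3' on the tag strand
    chrom: str
    start: int  # 1-based inclusive genomic window
    end: int
    strand: str
    structure: str
    pair_count: int
    mature_offset: int  # 1-based position of the mature within the window
    verdict: str = "rejected"
    reason: str = ""


@dataclass
class MirnaRecord:
    mirna_id: str
    mature_seq: str  # RNA
    status: str  # known | novel
    family: str | None = None
    precursor: HairpinCandidate | None = None
    tags: list[str] = field(default_factory=list)  # contributing DNA tags
    counts: dict[str, int] = field(default_factory=dict)  # per-sample reads
    locus: tuple[str, int, str] | None = None  # representative mature locus


def reference_family(ref_id: str) -> str | None:
    m = _FAMILY_RE.search(ref_id)
    return f"miR{m.group(2)}" if m else None


def _terminal_trim_match(tag: str, ref: str, max_trim: int = 2) -> bool:
    if abs(len(tag) - len(ref)) > max_trim:
        return False
    short, long_ = (tag, ref) if len(tag) <= len(ref) else (ref, tag)
    return short in long_


def match_known(catalog: TagCatalog, reference: dict[str, str]) -> list[MirnaRecord]:
    """Assign tags to known miRNAs from a mature(+precursor) reference.

    Precursor entries (longer than 30 nt) only provide context and are not
    matched directly. Reference IDs must be unique (enforced by the FASTA
    reader); each reference mature yields at most one record aggregating all
    matching tags.
    """
    matures = {rid: to_dna(seq) for rid, seq in reference.items() if len(seq) <= 30}
    samples = list(catalog.counts.columns)
    records: list[MirnaRecord] = []
    for rid in sorted(matures):
        ref = matures[rid]
        matching = [t for t in catalog.tags if _terminal_trim_match(t, ref)]
        if not matching:
            continue
        counts = dict.fromkeys(samples, 0)
        for t in matching:
            row = catalog.counts.loc[t]
            for s in samples:
                counts[s] += int(row[s])
        locus = None
        for t in matching:
            if catalog.loci.get(t):
                locus = catalog.loci[t][0]
                break
        records.append(
            MirnaRecord(
                mirna_id=rid,
                mature_seq=to_rna(reference[rid]),
                status="known",
                family=reference_family(rid),
                tags=matching,
                counts=counts,
                locus=locus,
            )
        )
    return records


def _check_hairpin(cand: HairpinCandidate, mature_len: int, window_seq: str) -> None:
    """Apply the acceptance rules, filling verdict and reason."""
    pairs = pair_table(cand.structure)
    m0 = cand.mature_offset - 1
    mature_pos = range(m0, m0 + mature_len)
    paired = [p for p in mature_pos if p in pairs]
    if len(paired) < max(14, mature_len - 3):
        cand.reason = f"insufficient stem pairing ({len(paired)} mature bases paired)"
        return
    if len(paired) / mature_len < 0.60:
        cand.reason = f"under 60% of mature bases paired ({len(paired)}/{mature_len})"
        return
    wobbles = sum(
        (window_seq[p], window_seq[pairs[p]]) not in WATSON_CRICK for p in paired
    )
    if wobbles > 0.25 * len(paired):
        cand.reason = f"too many G:U wobbles in the mature duplex ({wobbles}/{len(paired)})"
        return
    partners = [pairs[p] for p in paired]
    left = [q for q in partners if q < m0]
    right = [q for q in partners if q >= m0 + mature_len]
    if left and right:
        cand.reason = "mature partners on both sides (no single stem arm)"
        return
    if len(left) + len(right) < len(partners):
        cand.reason = "mature pairs with itself"
        return
    # single terminal loop on the mature-arm path: incidental pairing inside
    # the loop is tolerated, a >2-pair internal stem is a genuine branch
    if right:  # mature on the 5' arm, loop is 3' of it
        lo, hi = max(paired), pairs[max(paired)]
    else:  # mature on the 3' arm, loop is 5' of it
        lo, hi = pairs[min(paired)], min(paired)
    inner_pairs = sum(1 for i in pairs if lo < i < hi) // 2
    if inner_pairs > 2:
        cand.reason = f"branched structure inside the terminal loop ({inner_pairs} pairs)"
        return
    cand.verdict = "accepted"
    cand.reason = ""


def _window_candidates(
    tag: str,
    locus: tuple[str, int, str],
    genome: dict[str, str],
    flank: int,
) -> list[tuple[int, int, int]]:
    """(genomic start0, genomic end0 exclusive, oriented mature offset0) windows."""
    chrom, start1, strand = locus
    g0, g1 = start1 - 1, start1 - 1 + len(tag)
    clen = len(genome[chrom])
    extents = sorted({min(30, flank), min(50, flank), flank})
    wins = []
    for ext in extents:
        if strand == "+":
            down = (g0, min(g1 + ext, clen))
            up = (max(g0 - ext, 0), g1)
            wins.append((down[0], down[1], 0))
            wins.append((up[0], up[1], (up[1] - up[0]) - len(tag)))
        else:
            down = (max(g0 - ext, 0), g1)  # downstream of a minus-strand tag
            up = (g0, min(g1 + ext, clen))
            wins.append((down[0], down[1], 0))
            wins.append((up[0], up[1], (up[1] - up[0]) - len(tag)))
    return wins


def call_novel(
    catalog: TagCatalog,
    genome: dict[str, str],
    known: list[MirnaRecord],
    flank: int = 80,
    min_count: int = 2,
    max_loci: int = 4,
) -> list[MirnaRecord]:
    """Call novel miRNAs from unexplained tags by hairpin folding.

    Tags already explained by a known record are skipped (known > novel);
    tags with fewer than ``min_count`` supporting reads or more than
    ``max_loci`` placements are not considered.
    """
    explained = {t for rec in known for t in rec.tags}
    samples = list(catalog.counts.columns)
    totals = catalog.total_counts()
    accepted: list[tuple[tuple[str, int], MirnaRecord]] = []
    for tag in catalog.tags:
        if tag in explained or int(totals[tag]) < min_count:
            continue
        placements = catalog.loci.get(tag) or []
        if not placements or len(placements) > max_loci:
            continue
        best: HairpinCandidate | None = None
        best_locus = None
        for locus in placements:
            chrom, _, strand = locus
            for w0, w1, off in _window_candidates(tag, locus, genome, flank):
                seq = genome[chrom][w0:w1]
                if strand == "-":
                    seq = revcomp_dna(seq)
                if seq[off : off + len(tag)] != tag:  # truncated into the mature
                    continue
                structure, pc = fold_nussinov(seq)
                cand = HairpinCandidate(
                    window_seq=to_rna(seq),
                    chrom=chrom,
                    start=w0 + 1,
                    end=w1,
                    strand=strand,
                    structure=structure,
                    pair_count=pc,
                    mature_offset=off + 1,
                )
                _check_hairpin(cand, len(tag), cand.window_seq)
                if best is None or (cand.verdict == "accepted", cand.pair_count) > (
                    best.verdict == "accepted",
                    best.pair_count,
                ):
                    best = cand
                    best_locus = locus
                if best.verdict == "accepted":
                    break
            if best is not None and best.verdict == "accepted":
                break
        if best is not None and best.verdict == "accepted":
            counts = {s: int(catalog.counts.loc[tag, s]) for s in samples}
            rec = MirnaRecord(
                mirna_id="",  # assigned below in coordinate order
                mature_seq=to_rna(tag),
                status="novel",
                precursor=best,
                tags=[tag],
                counts=counts,
                locus=best_locus,
            )
            accepted.append(((best.chrom, best.start), rec))
    accepted.sort(key=lambda x: (x[0][0], x[0][1], x[1].mature_seq))
    out = []
    for i, (_, rec) in enumerate(accepted):
        rec.mirna_id = f"novel_{i+1}"
        out.append(rec)
    return out


def assign_family(
    novel: MirnaRecord, reference: dict[str, str], max_distance: int = 3
) -> str | None:
    """Family of the closest reference mature by edit distance, if close enough.

    Ties go to the lexicographically smallest family name.
    """
    best: tuple[int, str] | None = None
    mature = to_rna(novel.mature_seq)
    for rid in sorted(reference):
        seq = reference[rid]
        if len(seq) > 30:
            continue
        fam = reference_family(rid)
        if fam is None:
            continue
        d = edlib.align(mature, to_rna(seq))["editDistance"]
        if d <= max_distance and (best is None or (d, fam) < best):
            best = (d, fam)
    return best[1] if best else None


def tissue_mirna_sets(
    records: list[MirnaRecord],
    sample_tissues: dict[str, str],
    min_count: int = 1,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-tissue miRNA sets and the Venn partition of their union.

    A miRNA belongs to a tissue when its replicate-summed count reaches
    ``min_count``. The partition dict is keyed by '+'-joined sorted tissue
    combinations (e.g. 'NW+TW+OW' for the fully shared set).
    """
    tissues = sorted(set(sample_tissues.values()))
    sets: dict[str, set[str]] = {t: set() for t in tissues}
    for rec in records:
        per_tissue: dict[str, int] = dict.fromkeys(tissues, 0)
        for s, n in rec.counts.items():
            per_tissue[sample_tissues[s]] += n
        for t in tissues:
            if per_tissue[t] >= min_count:
                sets[t].add(rec.mirna_id)
    partition: dict[str, int] = {}
    union = set().union(*sets.values()) if sets else set()
    for mid in union:
        key = "+".join(sorted(t for t in tissues if mid in sets[t]))
        partition[key] = partition.get(key, 0) + 1
    return sets, partition
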