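"""miRNA target prediction by complementarity with an expectation score.

Plant miRNAs recognize near-perfectly complementary sites on their target
transcripts. Each candidate duplex is scored by a cumulative mispairing
penalty ("expectation"): mismatches cost 1.0, G:U wobbles 0.5 and
single-nucleotide bulges 2.0, with every penalty doubled inside the seed
region (miRNA positions 2-13 counted from the 5' end). Sites scoring at or
below a cutoff (default 3.0) are reported, together with the putative
cleavage position on the transcript, opposite miRNA positions 10/11.

The scan considers, at every transcript start, the gapless duplex plus all
single-bulge variants (one extra transcript base, or one unpaired miRNA
base), with the bulge never between miRNA positions 10 and 11. Scanning is
vectorized with prefix-sum arrays; reported hits are reconstructed as
explicit column-by-column alignments and re-scored, so the fast path and the
alignment model cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import WATSON_CRICK, WOBBLE, check_alphabet, to_rna

__all__ = [
    "ScoringScheme",
    "DuplexAlignment",
    "TargetHit",
    "expectation_score",
    "scan_transcript",
    "predict_targets",
]

MATCH, GU, MISMATCH, GAP = "match", "GU", "mismatch", "gap"

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty constants for duplex scoring (config-exposed)."""

    mismatch: float = 1.0
    gu: float = 0.5
    gap: float = 2.0
    seed_start: int = 2  # 1-based miRNA positions with doubled penalties
    seed_end: int = 13
    double_factor: float = 2.0

    def weight(self, mirna_pos: int) -> float:
        return self.double_factor if self.seed_start <= mirna_pos <= self.seed_end else 1.0


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class DuplexAlignment:
    """A miRNA:target-site duplex.

    ``mirna_aln`` is the miRNA 5'->3' with ``-`` where a transcript base is
    bulged; ``site_aln`` is the target site written 3'->5' of the transcript
    (so the two strings line up antiparallel), with ``-`` where a miRNA base
    is bulged. ``pairing`` holds one code per alignment column.
    ``site_start``/``site_end`` are 1-based inclusive transcript coordinates.
    """

    mirna_seq: str
    target_site: str  # 5'->3' of the transcript
    mirna_aln: str
    site_aln: str
    pairing: list[str]
    site_start: int
    site_end: int

    def __post_init__(self) -> None:
        if len(self.mirna_aln) != len(self.site_aln) or len(self.pairing) != len(self.mirna_aln):
            raise ValueError("alignment strings and pairing codes must have equal length")


def _pair_code(a: str, b: str) -> str:
    if (a, b) in WATSON_CRICK:
        return MATCH
    if (a, b) in WOBBLE:
        return GU
    return MISMATCH


def expectation_score(alignment: DuplexAlignment, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Sum the penalty of every alignment column.

    Validates each stated pairing code against the aligned bases; a gap
    column's miRNA position (for seed doubling) is the position of the last
    preceding miRNA base.
    """
    score = 0.0
    mirna_pos = 0
    for col, code in enumerate(alignment.pairing):
        m, t = alignment.mirna_aln[col], alignment.site_aln[col]
        if code == GAP:
            if m != "-" and t != "-":
                raise ValueError(f"column {col}: gap code without a gap character")
            pos = mirna_pos + 1 if m != "-" else mirna_pos
            if m != "-":
                mirna_pos += 1
            score += scheme.gap * scheme.weight(max(pos, 1))
            continue
        if m == "-" or t == "-":
            raise ValueError(f"column {col}: gap character with code {code!r}")
        mirna_pos += 1
        expected = _pair_code(m, t)
        if expected != code:
            raise ValueError(
                f"column {col}: pairing code {code!r} inconsistent with bases {m}:{t}"
            )
        if code == MISMATCH:
            score += scheme.mismatch * scheme.weight(mirna_pos)
        elif code == GU:
            score += scheme.gu * scheme.weight(mirna_pos)
    return score


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    expectation: float
    alignment: DuplexAlignment
    cleavage_pos: int  # transcript base opposite miRNA position 10; cut on its 5' side
    site_start: int = field(init=False)
    site_end: int = field(init=False)

    def __post_init__(self) -> None:
        self.site_start = self.alignment.site_start
        self.site_end = self.alignment.site_end


def _penalty_matrix(mirna: str, scheme: ScoringScheme) -> np.ndarray:
    """P[i, b] = penalty of miRNA position i+1 opposite transcript base b."""
    L = len(mirna)
    P = np.zeros((L, 4))
    for i, m in enumerate(mirna):
        w = scheme.weight(i + 1)
        for b, bi in _ENC.items():
            code = _pair_code(m, b)
            P[i, bi] = 0.0 if code == MATCH else (scheme.gu if code == GU else scheme.mismatch) * w
    return P


def _build_alignment(
    mirna: str, transcript: str, s0: int, variant: str, g: int
) -> DuplexAlignment:
    """Construct the explicit alignment for one candidate site.

    ``s0`` is the 0-based site start; ``variant`` is ``gapless``,
    ``tbulge`` (extra transcript base after miRNA position g) or ``mbulge``
    (miRNA base g unpaired). Columns run miRNA 5'->3'.
    """
    L = len(mirna)
    if variant == "gapless":
        site = transcript[s0 : s0 + L]
        cols = [(i, s0 + L - 1 - i) for i in range(L)]  # (mirna idx, transcript idx)
    elif variant == "tbulge":
        site = transcript[s0 : s0 + L + 1]
        cols = []
        for i in range(g):
            cols.append((i, s0 + L - i))
        cols.append((None, s0 + L - g))  # bulged transcript base
        for i in range(g, L):
            cols.append((i, s0 + L - 1 - i))
    elif variant == "mbulge":
        site = transcript[s0 : s0 + L - 1]
        cols = []
        for i in range(g - 1):
            cols.append((i, s0 + L - 2 - i))
        cols.append((g - 1, None))  # bulged miRNA base
        for i in range(g, L):
            cols.append((i, s0 + L - 2 - i + 1))  # one transcript base fewer consumed
    else:  # pragma: no cover
        raise ValueError(variant)
    m_aln, s_aln, codes = [], [], []
    for mi, ti in cols:
        if mi is None:
            m_aln.append("-")
            s_aln.append(transcript[ti])
            codes.append(GAP)
        elif ti is None:
            m_aln.append(mirna[mi])
            s_aln.append("-")
            codes.append(GAP)
        else:
            m_aln.append(mirna[mi])
            s_aln.append(transcript[ti])
            codes.append(_pair_code(mirna[mi], transcript[ti]))
    return DuplexAlignment(
        mirna_seq=mirna,
        target_site=site,
        mirna_aln="".join(m_aln),
        site_aln="".join(s_aln),
        pairing=codes,
        site_start=s0 + 1,
        site_end=s0 + len(site),
    )


def _cleavage_pos(alignment: DuplexAlignment) -> int:
    """1-based transcript coordinate of the base opposite miRNA position 10."""
    # walk columns, tracking miRNA position and transcript coordinate (3'->5')
    t = alignment.site_end
    pos = 0
    for col, code in enumerate(alignment.pairing):
        m = alignment.mirna_aln[col]
        s = alignment.site_aln[col]
        if m != "-":
            pos += 1
        if pos == 10 and m != "-":
            return t
        if s != "-":
            t -= 1
    raise ValueError("miRNA shorter than 10 nt has no cleavage position")


def scan_transcript(
    mirna: str,
    transcript: str,
    cutoff: float = 3.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list[TargetHit]:
    """Scan a transcript for target sites of one miRNA.

    Returns the best alignment per site start with expectation <= cutoff,
    sorted best-first (ties by site start). Tie-break among variants at one
    start: gapless, then smaller bulge position, transcript bulge before
    miRNA bulge.
    """
    m = to_rna(mirna)
    t = to_rna(transcript)
    check_alphabet(m)
    check_alphabet(t.replace("N", ""))  # N never pairs; treat as mismatch
    L = len(m)
    n = len(t)
    if n < L:
        raise ValueError("transcript shorter than miRNA")
    enc = np.array([_ENC.get(c, 0) for c in t], dtype=np.intp)
    is_n = np.array([c == "N" for c in t])
    P = _penalty_matrix(m, scheme)
    # prefix[s, i] = sum over miRNA positions 1..i of penalty opposite t[s+L-i']
    nstart = n - L + 1
    pref = np.zeros((nstart + 1, L + 1))  # extra row for s = nstart (prefixes only)
    for i in range(1, L + 1):
        idx_max = nstart + 1 if i > 1 else nstart  # t index s+L-i must be < n
        ts = np.arange(idx_max) + L - i
        valid = ts < n
        col = np.zeros(nstart + 1)
        pen = P[i - 1, enc[ts[valid]]]
        # an N in the transcript is always a plain mismatch
        pen = np.where(is_n[ts[valid]], scheme.mismatch * scheme.weight(i), pen)
        col[: idx_max][valid] = pen
        pref[:, i] = pref[:, i - 1] + col
    gapless = pref[:nstart, L]

    dgap = np.array([scheme.gap * scheme.weight(g) for g in range(L + 1)])
    # Candidate space per site start s (0-based): gapless s in [0, n-L];
    # transcript bulge s in [0, n-L-1]; miRNA bulge s in [1, n-L]. All
    # variants are stacked on the common start grid in priority order
    # (gapless first, then ascending bulge position, transcript bulge before
    # miRNA bulge); penalties are multiples of 0.25 so float sums are exact
    # and first-minimum tie-breaking is well defined.
    variant_rows: list[tuple[str, int, np.ndarray]] = [("gapless", 0, gapless)]
    bulge_positions = [g for g in range(1, L) if g not in (10, 11)]
    for g in bulge_positions:
        # transcript bulge after miRNA position g: site [s, s+L], score =
        # prefix_g(s+1) + gap + suffix_{>g}(s)
        row = np.full(nstart, np.inf)
        smax = n - L - 1
        if smax >= 0:
            row[: smax + 1] = (
                pref[1 : smax + 2, g] + dgap[g] + (pref[: smax + 1, L] - pref[: smax + 1, g])
            )
        variant_rows.append(("tbulge", g, row))
        # miRNA bulge at position g (g >= 2): site [s, s+L-2], score =
        # prefix_{g-1}(s-1) + gap + suffix_{>g}(s)
        if g >= 2:
            row_m = np.full(nstart, np.inf)
            row_m[1:nstart] = (
                pref[: nstart - 1, g - 1]
                + dgap[g]
                + (pref[1:nstart, L] - pref[1:nstart, g])
            )
            variant_rows.append(("mbulge", g, row_m))
    stack = np.vstack([r[2] for r in variant_rows])
    best_idx = np.argmin(stack, axis=0)  # first occurrence wins ties
    best_score = stack[best_idx, np.arange(nstart)]
    hits: list[TargetHit] = []
    for s in np.flatnonzero(best_score <= cutoff + 1e-9):
        s = int(s)
        variant, g, _ = variant_rows[int(best_idx[s])]
        aln = _build_alignment(m, t, s, variant, g)
        exp = expectation_score(aln, scheme)
        hits.append(
            TargetHit(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                expectation=exp,
                alignment=aln,
                cleavage_pos=_cleavage_pos(aln),
            )
        )
    hits.sort(key=lambda h: (h.expectation, h.site_start))
    return hits


def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = 3.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[list[TargetHit], list[TargetHit]]:
    """Scan every miRNA against every transcript.

    Returns ``(all_hits, best_per_pair)``; the second list keeps the single
    lowest-expectation hit per (miRNA, transcript) pair for network use.
    Transcript IDs must be unique (dict input enforces this upstream of the
    file layer, which checks on read).
    """
    all_hits: list[TargetHit] = []
    best: dict[tuple[str, str], TargetHit] = {}
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            for hit in scan_transcript(
                mirnas[mid], transcripts[tid], cutoff, scheme, mirna_id=mid, transcript_id=tid
            ):
                all_hits.append(hit)
                key = (mid, tid)
                cur = best.get(key)
                if cur is None or (hit.expectation, hit.site_start) < (
                    cur.expectation,
                    cur.site_start,
                ):
                    best[key] = hit
    all_hits.sort(key=lambda h: (h.mirna_id, h.transcript_id, h.expectation, h.site_start))
    return all_hits, [best[k] for k in sorted(best)]
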