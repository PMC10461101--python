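"""Target-scoring tests: hand-evaluated penalties and a brute-force scan oracle."""

from __future__ import annotations

import numpy as np
import pytest

from mirwoodnet._seq import WATSON_CRICK, WOBBLE, revcomp_rna
from mirwoodnet.targets import (
    GAP,
    GU,
    MATCH,
    MISMATCH,
    DuplexAlignment,
    ScoringScheme,
    expectation_score,
    predict_targets,
    scan_transcript,
)


def perfect_alignment(mirna: str) -> DuplexAlignment:
    site = revcomp_rna(mirna)
    return DuplexAlignment(
        mirna_seq=mirna,
        target_site=site,
        mirna_aln=mirna,
        site_aln=site[::-1],
        pairing=[MATCH] * len(mirna),
        site_start=1,
        site_end=len(site),
    )


def _mutate(aln: DuplexAlignment, pos1: int, code: str) -> DuplexAlignment:
    """Force a mismatch or wobble at miRNA position pos1 (1-based)."""
    i = pos1 - 1
    m = aln.mirna_aln[i]
    if code == MISMATCH:
        new = {"A": "A", "C": "C", "G": "A", "U": "C"}[m]  # cannot pair with m
    else:  # GU wobble
        new = {"G": "U", "U": "G"}[m]
    site_aln = aln.site_aln[:i] + new + aln.site_aln[i + 1 :]
    pairing = list(aln.pairing)
    pairing[i] = code
    return DuplexAlignment(
        mirna_seq=aln.mirna_seq,
        target_site=site_aln[::-1],
        mirna_aln=aln.mirna_aln,
        site_aln=site_aln,
        pairing=pairing,
        site_start=aln.site_start,
        site_end=aln.site_end,
    )


class TestExpectationScore:
    mirna = "ACGGUACGUACGUACGUACGU"

    def test_perfect_complement_scores_zero(self):
        assert expectation_score(perfect_alignment(self.mirna)) == 0.0

    def test_single_seed_mismatch_doubled(self):
        aln = _mutate(perfect_alignment(self.mirna), 5, MISMATCH)
        assert expectation_score(aln) == 2.0

    def test_wobble_outside_seed_plus_terminal_mismatch(self):
        aln = _mutate(perfect_alignment(self.mirna), 20, GU)
        aln = _mutate(aln, 1, MISMATCH)
        assert expectation_score(aln) == 1.5

    def test_inconsistent_code_rejected(self):
        aln = perfect_alignment(self.mirna)
        bad = DuplexAlignment(
            mirna_seq=aln.mirna_seq,
            target_site=aln.target_site,
            mirna_aln=aln.mirna_aln,
            site_aln=aln.site_aln,
            pairing=[MISMATCH] + list(aln.pairing[1:]),
            site_start=1,
            site_end=len(aln.target_site),
        )
        with pytest.raises(ValueError):
            expectation_score(bad)

    def test_monotone_in_added_penalties(self):
        rng = np.random.default_rng(8)
        aln = perfect_alignment(self.mirna)
        score = 0.0
        positions = rng.permutation(np.arange(1, len(self.mirna) + 1))
        for pos in positions[:8]:
            code = MISMATCH if rng.random() < 0.5 else GU
            if code == GU and self.mirna[pos - 1] not in "GU":
                code = MISMATCH
            aln = _mutate(aln, int(pos), code)
            new = expectation_score(aln)
            assert new >= score
            score = new


# --- brute-force scan oracle -------------------------------------------


def _col_penalty(m: str, t: str, pos: int, scheme: ScoringScheme) -> float:
    w = scheme.double_factor if scheme.seed_start <= pos <= scheme.seed_end else 1.0
    if (m, t) in WATSON_CRICK:
        return 0.0
    if (m, t) in WOBBLE:
        return scheme.gu * w
    return scheme.mismatch * w


def oracle_scan(mirna: str, transcript: str, cutoff: float, scheme=ScoringScheme()):
    """Position-by-position enumeration of every candidate alignment.

    Candidate space and priority mirror the documented contract: per start,
    gapless first, then ascending bulge position with the transcript bulge
    before the miRNA bulge; strictly smaller scores win.
    """
    L, n = len(mirna), len(transcript)
    results = {}
    for s in range(n - L + 1):
        cands = []
        # gapless
        score = sum(
            _col_penalty(mirna[i], transcript[s + L - 1 - i], i + 1, scheme) for i in range(L)
        )
        cands.append((score, "gapless", 0))
        for g in [g for g in range(1, L) if g not in (10, 11)]:
            gapw = scheme.gap * (
                scheme.double_factor if scheme.seed_start <= g <= scheme.seed_end else 1.0
            )
            if s + L < n:  # transcript bulge: site s..s+L
                sc = gapw
                for i in range(1, g + 1):
                    sc += _col_penalty(mirna[i - 1], transcript[s + L + 1 - i], i, scheme)
                for i in range(g + 1, L + 1):
                    sc += _col_penalty(mirna[i - 1], transcript[s + L - i], i, scheme)
                cands.append((sc, "tbulge", g))
            if g >= 2 and s >= 1:  # miRNA bulge: site s..s+L-2
                sc = gapw
                for i in range(1, g):
                    sc += _col_penalty(mirna[i - 1], transcript[s + L - 1 - i], i, scheme)
                for i in range(g + 1, L + 1):
                    sc += _col_penalty(mirna[i - 1], transcript[s + L - i], i, scheme)
                cands.append((sc, "mbulge", g))
        best = cands[0]
        for c in cands[1:]:
            if c[0] < best[0]:
                best = c
        if best[0] <= cutoff:
            results[s + 1] = best
    return results


def test_exact_complement_site_found_with_cleavage_site():
    mirna = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt
    tx = "AAGG" + revcomp_rna(mirna) + "CAAGGAGCAUCAUCA"
    hits = scan_transcript(mirna, tx, cutoff=0.0)
    assert len(hits) == 1
    h = hits[0]
    assert h.expectation == 0.0
    assert (h.site_start, h.site_end) == (5, 25)
    # slicing between bases opposite miRNA positions 10 and 11
    assert h.cleavage_pos == h.site_start + len(mirna) - 10


def test_scan_matches_bruteforce_oracle_on_random_transcript():
    rng = np.random.default_rng(17)
    mirna = "".join(rng.choice(list("ACGU"), 21))
    tx = list(rng.choice(list("ACGU"), 2000))
    # plant a perfect site, a seed-mutated site and a bulged site
    site = list(revcomp_rna(mirna))
    tx[100 : 100 + 21] = site
    mut = site.copy()
    mut[5] = {"A": "A", "C": "C", "G": "A", "U": "C"}[mut[5]]
    tx[400 : 400 + 21] = mut
    bulged = site[:7] + ["A"] + site[7:]
    tx[800 : 800 + 22] = bulged
    tx = "".join(tx)
    cutoff = 4.5
    hits = scan_transcript(mirna, tx, cutoff=cutoff)
    got = {h.site_start: h.expectation for h in hits}
    expected = {s: sc for s, (sc, _, _) in oracle_scan(mirna, tx, cutoff).items()}
    assert got == expected
    assert 101 in got and got[101] == 0.0
    # variants also match, not only scores
    variants = {h.site_start: (h.site_end - h.site_start + 1) for h in hits}
    for s, (sc, var, g) in oracle_scan(mirna, tx, cutoff).items():
        ln = {"gapless": 21, "tbulge": 22, "mbulge": 20}[var]
        assert variants[s] == ln, (s, var)


def test_cutoff_zero_returns_only_perfect_sites():
    rng = np.random.default_rng(2)
    mirna = "".join(rng.choice(list("ACGU"), 20))
    tx = "".join(rng.choice(list("ACGU"), 500)) + revcomp_rna(mirna)
    hits = scan_transcript(mirna, tx, cutoff=0.0)
    assert all(h.expectation == 0.0 for h in hits)
    assert any(h.site_start == 501 for h in hits)


def test_predict_targets_order_invariant_and_best_per_pair():
    rng = np.random.default_rng(9)
    mirnas = {"m1": "".join(rng.choice(list("ACGU"), 21))}
    t1 = "".join(rng.choice(list("ACGU"), 300)) + revcomp_rna(mirnas["m1"]).replace("U", "U")
    t2 = "".join(rng.choice(list("ACGU"), 400))
    a = predict_targets(mirnas, {"tA": t1, "tB": t2})
    b = predict_targets(mirnas, {"tB": t2, "tA": t1})
    key = lambda h: (h.mirna_id, h.transcript_id, h.site_start, h.expectation)
    assert [key(h) for h in a[0]] == [key(h) for h in b[0]]
    best = {(h.mirna_id, h.transcript_id) for h in a[1]}
    assert len(best) == len(a[1])  # one best hit per pair
    assert ("m1", "tA") in best
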