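"""Read cleaning, exact mapping (vs naive oracle), masking and profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirwoodnet._seq import revcomp_dna
from mirwoodnet.reads import (
    CleanStats,
    ReadSet,
    TagCatalog,
    clean_reads,
    collapse_and_map,
    first_base_profile,
    length_profile,
    mask_annotated,
    phred_q,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _read(seq: str, q: int = 35) -> tuple[str, list[int]]:
    return seq, [q] * len(seq)


@pytest.mark.parametrize("err,q", [(0.01, 20.0), (1.0, 0.0), (0.001, 30.0)])
def test_phred_definition(err, q):
    assert phred_q(err) == pytest.approx(q)


def test_phred_domain_error():
    with pytest.raises(ValueError):
        phred_q(0.0)


class TestCleanReads:
    def test_filters(self):
        good = _read("ACGTACGTACGTACGTACGT" + ADAPTER + "ACGTACGTA")
        short = _read("ACGTACGTACGTACGTA"[:17] + ADAPTER + "ACGTACGTACGT")
        many_n = _read("ACGNNNGTACGTACGTACGT" + ADAPTER + "ACGTACGTA")
        seq, qual = _read("ACGTACGTACGTACGTACGT" + ADAPTER + "ACGTACGTA")
        low_tail = (seq, qual[:18] + [10, 10] + qual[20:])
        raw = ReadSet(sample_id="s", reads=[good, short, many_n, low_tail])
        cleaned, stats = clean_reads(raw, ADAPTER)
        assert stats.raw_reads == 4
        assert stats.clean_reads == 1
        assert [s for s, _ in cleaned.reads] == ["ACGTACGTACGTACGTACGT"]

    def test_long_reads_counted_clean_but_not_srna(self):
        long_insert = "ACGT" * 9  # 36 nt, no adapter hit
        raw = ReadSet(sample_id="s", reads=[_read(long_insert), _read("ACGT" * 5 + ADAPTER)])
        cleaned, stats = clean_reads(raw, ADAPTER)
        assert stats.clean_reads == 2
        assert stats.total_srna == 1

    def test_accounting_identity(self):
        rng = np.random.default_rng(4)
        reads = []
        for _ in range(300):
            n = int(rng.integers(10, 31))
            seq = "".join(rng.choice(list("ACGTN"), n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            q = rng.integers(5, 41, n + len(ADAPTER)).tolist()
            reads.append((seq + ADAPTER, q))
        cleaned, stats = clean_reads(ReadSet(sample_id="s", reads=reads), ADAPTER)
        discarded = stats.raw_reads - stats.clean_reads
        assert discarded >= 0
        assert stats.total_srna <= stats.clean_reads <= stats.raw_reads

    def test_bad_adapter_rejected(self):
        with pytest.raises(ValueError):
            clean_reads(ReadSet(sample_id="s", reads=[_read("ACGT" * 6)]), "ACGU" * 3)


class TestCollapseAndMap:
    def test_exact_mapper_matches_naive_substring_search(self):
        rng = np.random.default_rng(12)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 50_000))}
        tags = []
        for _ in range(200):
            n = int(rng.integers(18, 26))
            if rng.random() < 0.5:  # genuine genomic tag, possibly minus strand
                i = int(rng.integers(0, 50_000 - n))
                t = genome["chr1"][i : i + n]
                if rng.random() < 0.5:
                    t = revcomp_dna(t)
            else:
                t = "".join(rng.choice(list("ACGT"), n))
            tags.append(t)
        clean = {"s1": ReadSet(sample_id="s1", reads=[_read(t) for t in tags])}
        catalog, mapped = collapse_and_map(clean, genome)
        for t in catalog.tags:
            naive = set()
            for i in range(len(genome["chr1"]) - len(t) + 1):
                seg = genome["chr1"][i : i + len(t)]
                if seg == t:
                    naive.add(("chr1", i + 1, "+"))
                if seg == revcomp_dna(t):
                    naive.add(("chr1", i + 1, "-"))
            assert set(catalog.loci[t]) == naive

    def test_unmapped_tag_flagged_and_counts_conserved(self):
        genome = {"chr1": "ACGT" * 3000}
        clean = {
            "s1": ReadSet(sample_id="s1", reads=[_read("ACGTACGTACGTACGTACGT")] * 3),
            "s2": ReadSet(sample_id="s2", reads=[_read("TTGACCTTGAGGAACCTTGG")] * 2),
        }
        catalog, mapped = collapse_and_map(clean, genome)
        assert catalog.counts.loc["ACGTACGTACGTACGTACGT", "s1"] == 3
        assert catalog.loci["TTGACCTTGAGGAACCTTGG"] == []
        assert mapped == {"s1": 3, "s2": 0}
        assert int(catalog.counts.sum().sum()) == 5

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            collapse_and_map({"s": ReadSet(sample_id="s", reads=[_read("ACGT" * 5)])}, {})


def test_mapping_ratio_matches_printed_accounting():
    st = CleanStats(sample_id="NW1", raw_reads=10_891_608, clean_reads=10_601_788,
                    total_srna=8_002_438, mapped_srna=7_378_835)
    st.compute_ratio()
    assert st.mapping_ratio == 92.21


class TestMasking:
    @pytest.fixture()
    def catalog(self):
        counts = pd.DataFrame(
            {"s1": [5, 3, 2]},
            index=["AAAACCCCGGGGTTTTACGT", "CCCCGGGGTTTTACGTAAAA", "GGGGTTTTACGTAAAACCCC"],
        )
        loci = {
            "AAAACCCCGGGGTTTTACGT": [("chr1", 100, "+")],  # inside mask
            "CCCCGGGGTTTTACGTAAAA": [("chr1", 100, "+"), ("chr1", 5000, "+")],
            "GGGGTTTTACGTAAAACCCC": [("chr1", 9000, "-")],
        }
        return TagCatalog(counts=counts, loci=loci)

    @pytest.fixture()
    def mask(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [300], "type": ["tRNA"]})

    def test_fully_masked_removed_partial_kept(self, catalog, mask):
        out = mask_annotated(catalog, mask)
        assert "AAAACCCCGGGGTTTTACGT" not in out.tags
        assert "CCCCGGGGTTTTACGTAAAA" in out.tags  # one unmasked locus
        assert "GGGGTTTTACGTAAAACCCC" in out.tags

    def test_idempotent(self, catalog, mask):
        once = mask_annotated(catalog, mask)
        twice = mask_annotated(once, mask)
        assert once.tags == twice.tags

    def test_empty_mask_is_identity(self, catalog):
        empty = pd.DataFrame({"chrom": [], "start": [], "end": [], "type": []})
        assert mask_annotated(catalog, empty).tags == catalog.tags

    def test_malformed_interval(self, catalog):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [50], "type": ["tRNA"]})
        with pytest.raises(ValueError):
            mask_annotated(catalog, bad)


class TestProfiles:
    def test_single_length_profile(self):
        counts = pd.DataFrame({"s1": [4, 6]}, index=["A" * 21, "C" * 21])
        cat = TagCatalog(counts=counts, loci={})
        prof = length_profile(cat)
        assert prof.loc[21] == 1.0
        assert prof.sum() == pytest.approx(1.0, abs=1e-12)

    def test_first_base_reported_in_rna_alphabet(self):
        counts = pd.DataFrame({"s1": [7, 3]}, index=["T" + "A" * 20, "T" + "C" * 19])
        cat = TagCatalog(counts=counts, loci={})
        mat = first_base_profile(cat)
        assert mat.loc[21, "U"] == 1.0
        assert mat.loc[20, "U"] == 1.0
        assert (mat.sum(axis=1)[mat.sum(axis=1) > 0] == 1.0).all()

    def test_synthetic_mode_and_u_bias(self, small_genome):
        from mirwoodnet.synth import simulate_reads

        cfg, genome = small_genome
        reads = simulate_reads(cfg, genome)
        clean = {}
        for s in genome.truth.samples[:3]:
            rs, _ = clean_reads(ReadSet(sample_id=s, reads=reads[s]), cfg.adapter_seq)
            clean[s] = rs
        catalog, _ = collapse_and_map(clean, genome.chroms)
        prof = length_profile(catalog)
        assert prof.idxmax() == 21
        mat = first_base_profile(catalog)
        # mature miRNAs were drawn with a 70% U start; background dilutes it
        assert mat.loc[21, "U"] > 0.4
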