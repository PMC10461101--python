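"""Synthetic reaction-wood small-RNA experiment with a machine-readable truth.

The generator emulates the data the pipeline consumes: a toy genome carrying
hairpin miRNA precursors at recorded loci, per-sample small-RNA FASTQ reads
(mature miRNAs with a ligated 3' adapter plus annotated and random
background), an mRNA expression matrix in which planted target genes are
anti-correlated with their miRNA, a transcription-factor layer with
co-expressed downstream genes, pathway labels with one over-represented
pathway, a transcriptome with planted complementary target sites, and qPCR
Ct tables derived from expression through Ct = a - b*log2(x).

Everything is driven by :class:`~mirwoodnet.config.SyntheticConfig`; a fixed
seed gives byte-identical output files. ``cfg.zero_noise()`` switches off
every stochastic nuisance so that the full pipeline must reproduce the
planted truth exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp_dna, revcomp_rna, to_dna, to_rna
from .config import SyntheticConfig

__all__ = [
    "MirnaTruth",
    "TruthTable",
    "Genome",
    "make_hairpin_precursor",
    "make_genome",
    "simulate_reads",
    "simulate_expression",
    "replicate_abundances",
    "simulate",
]

_BASES = np.array(list("ACGT"))
_RNA_BASES = "ACGU"
_NOPAIR = {  # for each partner base, substitutions that cannot pair with it
    "A": "AC",
    "C": "AC",
    "G": "AG",
    "U": "CU",
}
_TF_FAMILIES = ("C3H", "MYB", "bZIP", "FAR1")
_KNOWN_FAMILIES = ("miR156", "miR159", "miR166", "miR172", "miR396", "miR408", "miR482", "miR535")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_hairpin_precursor(
    mature: str, loop_len: int = 6, n_bulges: int = 0, seed: int | np.random.Generator = 0
) -> str:
    """Build a stem-loop precursor carrying ``mature`` on its 5' arm.

    The 3' arm is the reverse complement of the mature with ``n_bulges``
    substitutions that cannot re-pair; the loop is drawn from {A, C} only so
    it cannot fold internally under the AU/GC/GU pairing rules.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 to close a hairpin")
    m = to_rna(mature)
    if not 18 <= len(m) <= 24:
        raise ValueError(f"mature length {len(m)} outside 18-24 nt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loop = "".join(rng.choice(list("AC"), loop_len))
    arm = list(revcomp_rna(m))
    if n_bulges > len(arm):
        raise ValueError("more bulges than arm positions")
    for pos in sorted(rng.choice(len(arm), size=n_bulges, replace=False)):
        partner = m[len(m) - 1 - pos]
        choices = [b for b in _NOPAIR[partner] if b != arm[pos]]
        arm[pos] = choices[rng.integers(0, len(choices))]
    return m + loop + "".join(arm)


@dataclass
class MirnaTruth:
    mirna_id: str
    status: str  # known | novel
    family: str | None
    mature_seq: str  # RNA
    precursor_seq: str  # RNA
    chrom: str = ""
    start: int = 0  # 1-based inclusive precursor locus
    end: int = 0
    strand: str = "+"
    tissue_abundance: dict[str, float] = field(default_factory=dict)
    sample_abundance: dict[str, float] = field(default_factory=dict)
    true_targets: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class TruthTable:
    mirnas: list[MirnaTruth]
    samples: list[str]
    tissues: list[str]
    tf_targets: list[str] = field(default_factory=list)  # TF genes among planted targets
    downstream: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    enriched_pathway: str = ""
    de_truth: dict[str, list[str]] = field(default_factory=dict)  # contrast -> miRNA ids
    qpcr_panel: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def novel(self) -> list[MirnaTruth]:
        return [m for m in self.mirnas if m.status == "novel"]

    @property
    def known(self) -> list[MirnaTruth]:
        return [m for m in self.mirnas if m.status == "known"]

    def to_json(self) -> str:
        def enc(m: MirnaTruth) -> dict:
            d = m.__dict__.copy()
            d["true_targets"] = [list(t) for t in m.true_targets]
            return d

        payload = {
            "mirnas": [enc(m) for m in self.mirnas],
            "samples": self.samples,
            "tissues": self.tissues,
            "tf_targets": self.tf_targets,
            "downstream": {k: [list(t) for t in v] for k, v in self.downstream.items()},
            "enriched_pathway": self.enriched_pathway,
            "de_truth": self.de_truth,
            "qpcr_panel": self.qpcr_panel,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        d = json.loads(text)
        mirnas = []
        for md in d["mirnas"]:
            md = dict(md)
            md["true_targets"] = [tuple(t) for t in md["true_targets"]]
            mirnas.append(MirnaTruth(**md))
        return cls(
            mirnas=mirnas,
            samples=d["samples"],
            tissues=d["tissues"],
            tf_targets=d["tf_targets"],
            downstream={k: [tuple(t) for t in v] for k, v in d["downstream"].items()},
            enriched_pathway=d["enriched_pathway"],
            de_truth=d["de_truth"],
            qpcr_panel=d["qpcr_panel"],
            warnings=d["warnings"],
        )


@dataclass
class Genome:
    chroms: dict[str, str]  # DNA
    features: pd.DataFrame  # chrom, source, type, start, end, strand, attr (1-based)
    truth: TruthTable
    reference: dict[str, str]  # known mature/precursor reference (RNA)


def _draw_mature(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    existing: list[str],
    length: int | None = None,
) -> str:
    lens = sorted(cfg.mature_len_weights)
    probs = np.array([cfg.mature_len_weights[l] for l in lens], dtype=float)
    probs /= probs.sum()
    while True:
        n = length if length is not None else int(rng.choice(lens, p=probs))
        seq = "".join(np.array(list(_RNA_BASES))[rng.integers(0, 4, n)])
        if rng.random() < cfg.u_start_frac:
            seq = "U" + seq[1:]
        # keep matures mutually distinguishable under the family rule (<=3 edits)
        if all(edlib.align(seq, e)["editDistance"] > 3 for e in existing):
            return seq


def _place_intervals(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    lengths: list[int],
    margin: int = 150,
) -> list[tuple[str, int]]:
    """Non-overlapping 0-based placements (chrom, start), away from chrom ends."""
    occupied: dict[str, list[tuple[int, int]]] = {f"chr{i+1}": [] for i in range(cfg.n_chrom)}
    out = []
    for ln in lengths:
        for _ in range(10_000):
            chrom = f"chr{rng.integers(1, cfg.n_chrom + 1)}"
            start = int(rng.integers(margin + 100, cfg.chrom_length - ln - margin - 100))
            if all(start + ln + margin <= a or b + margin <= start for a, b in occupied[chrom]):
                occupied[chrom].append((start, start + ln))
                out.append((chrom, start))
                break
        else:
            raise ValueError("chromosomes too small to place all planted features")
    return out


def replicate_abundances(
    base: float, n: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Replicate-level abundances: multiplicative log-normal noise around a
    tissue mean (``noise_sd`` is the sd of the log2 deviation)."""
    return base * np.exp2(noise_sd * rng.standard_normal(n))


def make_genome(cfg: SyntheticConfig) -> Genome:
    """Build the toy genome, its annotation, the miRNA reference and truth."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    n_mirna = cfg.n_known_mirnas + cfg.n_novel_mirnas
    matures: list[str] = []
    for _ in range(n_mirna):
        matures.append(_draw_mature(rng, cfg, matures))
    precursors = [
        make_hairpin_precursor(m, cfg.loop_len, int(rng.integers(0, cfg.max_bulges + 1)), rng)
        for m in matures
    ]

    # decoy non-miRNA features per chromosome (masking targets)
    decoys = []  # (type, length)
    for _ in range(cfg.n_chrom):
        decoys += [("rRNA", 300), ("rRNA", 250), ("tRNA", 80), ("snRNA", 150), ("snoRNA", 120), ("repeat_region", 400)]
    lengths = [len(p) for p in precursors] + [ln for _, ln in decoys]
    placements = _place_intervals(rng, cfg, lengths)

    chrom_arrays = {
        f"chr{i+1}": _BASES[rng.integers(0, 4, cfg.chrom_length)] for i in range(cfg.n_chrom)
    }

    mirnas: list[MirnaTruth] = []
    feat_rows = []
    for idx in range(n_mirna):
        chrom, start0 = placements[idx]
        pre_dna = to_dna(precursors[idx])
        strand = "+" if rng.random() < 0.5 else "-"
        ins = pre_dna if strand == "+" else revcomp_dna(pre_dna)
        chrom_arrays[chrom][start0 : start0 + len(ins)] = list(ins)
        known = idx < cfg.n_known_mirnas
        if known:
            fam = _KNOWN_FAMILIES[idx % len(_KNOWN_FAMILIES)]
            letter = "abc"[idx // len(_KNOWN_FAMILIES)]
            mid = f"hbr-{fam}{letter}"
        else:
            fam = None
            mid = f"novel_{idx - cfg.n_known_mirnas + 1}"
        mirnas.append(
            MirnaTruth(
                mirna_id=mid,
                status="known" if known else "novel",
                family=fam,
                mature_seq=matures[idx],
                precursor_seq=precursors[idx],
                chrom=chrom,
                start=start0 + 1,
                end=start0 + len(pre_dna),
                strand=strand,
            )
        )
        feat_rows.append(
            (chrom, "mirwoodnet", "miRNA_primary_transcript", start0 + 1, start0 + len(pre_dna), strand, f"ID={mid}")
        )
    for k, (dtype, ln) in enumerate(decoys):
        chrom, start0 = placements[n_mirna + k]
        feat_rows.append((chrom, "mirwoodnet", dtype, start0 + 1, start0 + ln, "+", f"ID=decoy_{dtype}_{k}"))

    features = pd.DataFrame(
        feat_rows, columns=["chrom", "source", "type", "start", "end", "strand", "attr"]
    ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)

    # A planted miRNA must be discoverable: like real annotated miRNAs, which
    # are by definition the loci that pass hairpin criteria, each embedded
    # precursor is verified in its genomic context (the discovery windows
    # include flanking genome sequence) and redrawn if an unlucky mature
    # (e.g. strongly self-complementary) folds out of register.
    from .discovery import _check_hairpin, _window_candidates, HairpinCandidate
    from .fold import fold_nussinov

    def _recoverable(m: MirnaTruth) -> bool:
        tag = to_dna(m.mature_seq)
        chrom_seq = "".join(chrom_arrays[m.chrom])
        if m.strand == "+":
            locus = (m.chrom, m.start, "+")
        else:
            locus = (m.chrom, m.end - len(tag) + 1, "-")
        for w0, w1, off in _window_candidates(tag, locus, {m.chrom: chrom_seq}, 80):
            seq = chrom_seq[w0:w1]
            if m.strand == "-":
                seq = revcomp_dna(seq)
            if seq[off : off + len(tag)] != tag:
                continue
            structure, pc = fold_nussinov(seq)
            cand = HairpinCandidate(
                window_seq=to_rna(seq), chrom=m.chrom, start=w0 + 1, end=w1,
                strand=m.strand, structure=structure, pair_count=pc, mature_offset=off + 1,
            )
            _check_hairpin(cand, len(tag), cand.window_seq)
            if cand.verdict == "accepted":
                return True
        return False

    for idx, m in enumerate(mirnas):
        for _attempt in range(60):
            if _recoverable(m):
                break
            new_mature = _draw_mature(rng, cfg, matures, length=len(m.mature_seq))
            matures[idx] = new_mature
            new_pre = make_hairpin_precursor(
                new_mature, cfg.loop_len, int(rng.integers(0, cfg.max_bulges + 1)), rng
            )
            precursors[idx] = new_pre
            m.mature_seq, m.precursor_seq = new_mature, new_pre
            ins = to_dna(new_pre) if m.strand == "+" else revcomp_dna(to_dna(new_pre))
            chrom_arrays[m.chrom][m.start - 1 : m.start - 1 + len(ins)] = list(ins)
        else:
            raise RuntimeError(f"could not plant a recoverable precursor for {m.mirna_id}")

    # reference FASTA content: known matures and precursors, plus two decoy
    # entries absent from the genome so matching is non-trivial
    reference: dict[str, str] = {}
    for m in mirnas:
        if m.status == "known":
            reference[m.mirna_id] = m.mature_seq
            reference[m.mirna_id.replace("miR", "MIR") + "-precursor"] = m.precursor_seq
    for j in range(2):
        decoy_mature = _draw_mature(rng, cfg, matures + list(reference.values()))
        matures.append(decoy_mature)
        reference[f"ath-miR90{j}a"] = decoy_mature

    truth = TruthTable(mirnas=mirnas, samples=cfg.samples, tissues=list(cfg.tissues))
    _plant_abundance(cfg, truth, rng)
    chroms = {c: "".join(a) for c, a in sorted(chrom_arrays.items())}
    return Genome(chroms=chroms, features=features, truth=truth, reference=reference)


def _plant_abundance(cfg: SyntheticConfig, truth: TruthTable, rng: np.random.Generator) -> None:
    """Plant per-tissue expected abundances and replicate-level noise.

    Abundances are stored as expected reads-per-million among miRNA reads,
    i.e. proportions x 1e6, so the pipeline's normalized abundances estimate
    them directly. Novel miRNAs carry the differential effects (cfg.de_fold),
    with up/down patterns balanced across tissues; two known miRNAs are made
    tissue-absent to exercise the per-tissue miRNA sets.
    """
    tissues = list(cfg.tissues)
    n_t = len(tissues)
    weights = {}
    patterns = []  # (tissue index, up or down)
    for i in range(cfg.n_novel_mirnas):
        patterns.append((i % n_t, 1 if (i // n_t) % 2 == 0 else -1))
    for idx, m in enumerate(truth.mirnas):
        base = float(rng.lognormal(math.log(200.0), 0.5))
        # the 21-nt class dominates plant sRNA libraries; make that a
        # property of abundance, not only of the species length draw
        if len(m.mature_seq) == 21:
            base *= 2.0
        w = np.full(n_t, base)
        if m.status == "novel":
            t_idx, sign = patterns[idx - cfg.n_known_mirnas]
            w[t_idx] = base * (cfg.de_fold if sign > 0 else 1.0 / cfg.de_fold)
        elif idx >= cfg.n_known_mirnas - 2:
            # tissue-specific known miRNAs (absent outside the last tissue)
            w = np.zeros(n_t)
            w[-1] = base
        weights[m.mirna_id] = w
    W = np.vstack([weights[m.mirna_id] for m in truth.mirnas])  # miRNA x tissue
    col = W.sum(axis=0)
    tissue_prop = W / col * 1e6
    # replicate-level multiplicative noise, then per-sample renormalization
    n_rep = cfg.n_samples_per_tissue
    for j, m in enumerate(truth.mirnas):
        m.tissue_abundance = {t: float(tissue_prop[j, k]) for k, t in enumerate(tissues)}
    sample_w = np.empty((len(truth.mirnas), n_t * n_rep))
    for k in range(n_t):
        for r in range(n_rep):
            noisy = np.array(
                [
                    replicate_abundances(W[j, k], 1, cfg.noise_sd, rng)[0] if W[j, k] > 0 else 0.0
                    for j in range(len(truth.mirnas))
                ]
            )
            sample_w[:, k * n_rep + r] = noisy / noisy.sum() * 1e6
    for j, m in enumerate(truth.mirnas):
        m.sample_abundance = {s: float(sample_w[j, i]) for i, s in enumerate(truth.samples)}
    # truth differential-abundance sets, on the planted (pseudocounted) scale
    contrasts = [(a, b) for i, a in enumerate(tissues) for b in tissues[i + 1 :]]
    for a, b in contrasts:
        key = f"{a}:{b}"
        ids = []
        for m in truth.mirnas:
            fc = (m.tissue_abundance[a] + 1.0) / (m.tissue_abundance[b] + 1.0)
            if fc >= 2.0 or fc <= 0.5:
                ids.append(m.mirna_id)
        truth.de_truth[key] = ids


def simulate_reads(
    cfg: SyntheticConfig, genome: Genome
) -> dict[str, list[tuple[str, list[int]]]]:
    """Simulate per-sample reads as (sequence, quality) lists.

    Each miRNA read is the mature sequence with the 3' adapter ligated and
    random fill out to the read length; background reads come from annotated
    decoy features, random genomic loci and unmappable junk. A configurable
    fraction of reads get a degraded 3' quality tail, N contamination, or a
    sub-18-nt insert, so every cleaning filter sees real work.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    truth = genome.truth
    decoy_feats = genome.features[genome.features["type"] != "miRNA_primary_transcript"]
    out: dict[str, list[tuple[str, list[int]]]] = {}
    mature_dna = [to_dna(m.mature_seq) for m in truth.mirnas]
    for s_i, sample in enumerate(truth.samples):
        w = np.array([m.sample_abundance[sample] for m in truth.mirnas])
        probs = (1.0 - cfg.background_frac) * w / w.sum()
        bg = cfg.background_frac
        probs = np.concatenate([probs, [0.4 * bg, 0.4 * bg, 0.2 * bg]])
        counts = rng.multinomial(cfg.depth, probs)
        inserts: list[str] = []
        for j, m in enumerate(truth.mirnas):
            inserts += [mature_dna[j]] * counts[j]
        n_decoy, n_rand, n_junk = counts[-3], counts[-2], counts[-1]
        for _ in range(n_decoy):
            row = decoy_feats.iloc[int(rng.integers(0, len(decoy_feats)))]
            ln = int(rng.integers(18, 29))
            lo = int(rng.integers(row["start"] - 1, max(row["end"] - ln, row["start"])))
            inserts.append(genome.chroms[row["chrom"]][lo : lo + ln])
        for _ in range(n_rand):
            chrom = f"chr{rng.integers(1, cfg.n_chrom + 1)}"
            ln = int(rng.integers(18, 29))
            lo = int(rng.integers(0, cfg.chrom_length - ln))
            inserts.append(genome.chroms[chrom][lo : lo + ln])
        for _ in range(n_junk):
            inserts.append(_rand_seq(rng, int(rng.integers(20, 31))))
        # nuisance classes, applied uniformly so composition is unbiased
        n_reads = len(inserts)
        u = rng.random(n_reads)
        shorten = u < cfg.short_frac
        degrade = (u >= cfg.short_frac) & (u < cfg.short_frac + cfg.degrade_frac)
        add_n = (u >= cfg.short_frac + cfg.degrade_frac) & (
            u < cfg.short_frac + cfg.degrade_frac + cfg.n_base_frac
        )
        reads: list[tuple[str, list[int]]] = []
        for i, ins in enumerate(inserts):
            if shorten[i]:
                ins = ins[: int(rng.integers(10, 17))]
            if add_n[i]:
                k = max(int(math.ceil(0.15 * len(ins))), 3)
                pos = rng.choice(len(ins), size=min(k, len(ins)), replace=False)
                ins = "".join("N" if p in set(pos.tolist()) else c for p, c in enumerate(ins))
            seq = ins + cfg.adapter_seq
            if len(seq) < cfg.read_len:
                seq += _rand_seq(rng, cfg.read_len - len(seq))
            seq = seq[: cfg.read_len]
            qual = rng.integers(36, 41, cfg.read_len)
            if degrade[i]:
                cut = int(rng.integers(10, max(len(ins), 11)))
                qual[cut:] = rng.integers(3, 16, cfg.read_len - cut)
            reads.append((seq, qual.tolist()))
        order = rng.permutation(n_reads)
        out[sample] = [reads[i] for i in order]
    return out


def _plant_site(rng: np.random.Generator, transcript: list[str], mature_rna: str) -> int:
    site = revcomp_dna(to_dna(mature_rna))
    pos = int(rng.integers(30, len(transcript) - len(site) - 30))
    transcript[pos : pos + len(site)] = list(site)
    return pos + 1


@dataclass
class ExpressionBundle:
    expression: pd.DataFrame  # genes x samples
    transcripts: dict[str, str]  # DNA
    tf_table: pd.DataFrame  # gene_id, family
    pathway_map: pd.DataFrame  # gene_id, pathway_id
    ct_table: pd.DataFrame


def simulate_expression(cfg: SyntheticConfig, genome: Genome) -> ExpressionBundle:
    """Generate the mRNA side: expression, transcriptome, TF and pathway
    tables, and qPCR Ct values.

    Planted target genes are decreasing affine functions of their miRNA's
    per-sample abundance plus Gaussian noise scaled for a theoretical
    Pearson r of ``-cfg.target_r``; each TF target additionally gets
    ``cfg.n_downstream_per_tf`` co-expressed genes at ``|r| = cfg.target_r``.
    Ct values follow Ct = ct_a - ct_b*log2(x) with the reference genes held
    constant.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    truth = genome.truth
    samples = truth.samples
    n_s = len(samples)
    gene_ids = [f"gene_{i+1:04d}" for i in range(cfg.n_genes)]

    # assign the planted target pairs to novel miRNAs (round-robin)
    novel = truth.novel
    pair_mirnas: list[MirnaTruth] = [novel[i % len(novel)] for i in range(cfg.n_target_pairs)]
    pair_mirnas.sort(key=lambda m: m.mirna_id)
    target_genes = gene_ids[: cfg.n_target_pairs]
    tf_target_genes = target_genes[: cfg.n_tf_targets]
    n_down = cfg.n_tf_targets * cfg.n_downstream_per_tf
    downstream_genes = gene_ids[cfg.n_target_pairs : cfg.n_target_pairs + n_down]

    expr = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    # background genes: independent log-normal noise around a gene base level
    for g in gene_ids:
        base = float(rng.lognormal(math.log(100.0), 0.6))
        expr.loc[g] = base * np.exp2(cfg.noise_sd * rng.standard_normal(n_s))

    noise_scale = math.sqrt(1.0 / cfg.target_r**2 - 1.0)
    if cfg.target_r < 0.8:
        truth.warnings.append(
            f"target_r={cfg.target_r} below 0.8: planted correlations cannot pass the filter"
        )

    def planted_profile(x: np.ndarray, sign: float, base: float) -> np.ndarray:
        z = (x - x.mean()) / x.std()
        noise = noise_scale * rng.standard_normal(n_s) if noise_scale > 0 else 0.0
        y = base * (1.0 + sign * 0.3 * (z + noise))
        return np.maximum(y, 1e-3)

    for m, g in zip(pair_mirnas, target_genes):
        x = np.array([m.sample_abundance[s] for s in samples])
        base = float(rng.lognormal(math.log(120.0), 0.3))
        expr.loc[g] = planted_profile(x, -1.0, base)
        m.true_targets.append((g, -cfg.target_r))
    truth.tf_targets = list(tf_target_genes)
    di = 0
    for tf in tf_target_genes:
        x = expr.loc[tf].to_numpy()
        for _ in range(cfg.n_downstream_per_tf):
            g = downstream_genes[di]
            di += 1
            sign = 1.0 if rng.random() < 0.5 else -1.0
            base = float(rng.lognormal(math.log(100.0), 0.3))
            expr.loc[g] = planted_profile(x, sign, base)
            truth.downstream.setdefault(tf, []).append((g, sign * cfg.target_r))

    # transcriptome with planted complementary sites
    transcripts = {g: list(_rand_seq(rng, cfg.transcript_len)) for g in gene_ids}
    for m, g in zip(pair_mirnas, target_genes):
        _plant_site(rng, transcripts[g], m.mature_seq)
    transcripts_str = {g: "".join(tl) for g, tl in transcripts.items()}

    # TF annotation: planted TF targets plus background TFs up to n_tfs
    tf_rows = [(g, _TF_FAMILIES[i % len(_TF_FAMILIES)]) for i, g in enumerate(tf_target_genes)]
    extra = cfg.n_tfs - len(tf_target_genes)
    background_pool = gene_ids[cfg.n_target_pairs + n_down :]
    for i in range(max(extra, 0)):
        tf_rows.append((background_pool[i], _TF_FAMILIES[i % len(_TF_FAMILIES)]))
    tf_table = pd.DataFrame(sorted(tf_rows), columns=["gene_id", "family"])

    # pathway labels: the enriched pathway is over-represented among network
    # genes (targets + downstream), rare elsewhere
    network_genes = set(target_genes) | set(downstream_genes)
    rows = []
    pathways = list(cfg.other_pathways)
    truth.enriched_pathway = cfg.enriched_pathway
    for g in gene_ids:
        in_net = g in network_genes
        if (in_net and rng.random() < 0.6) or (not in_net and rng.random() < 0.05):
            rows.append((g, cfg.enriched_pathway))
        else:
            rows.append((g, pathways[int(rng.integers(0, len(pathways)))]))
    pathway_map = pd.DataFrame(rows, columns=["gene_id", "pathway_id"])

    ct_table = _make_ct_table(cfg, truth, expr, rng)
    return ExpressionBundle(
        expression=expr,
        transcripts=transcripts_str,
        tf_table=tf_table,
        pathway_map=pathway_map,
        ct_table=ct_table,
    )


def _make_ct_table(
    cfg: SyntheticConfig, truth: TruthTable, expr: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Ct values for a validation panel of miRNAs and target genes.

    Three technical replicates per (sample, assay); references (U6 for
    miRNAs, Ubiquitin for genes) are held at constant expression.
    """
    panel_mirnas = [m for m in truth.novel if m.true_targets][:6]
    panel_genes = [m.true_targets[0][0] for m in panel_mirnas]
    truth.qpcr_panel = {
        "mirnas": [m.mirna_id for m in panel_mirnas],
        "genes": panel_genes,
    }
    ct_noise = 0.2 * cfg.noise_sd
    rows = []

    def add(sample: str, gene: str, x: float, is_ref: bool, assay: str) -> None:
        ct0 = cfg.ct_a - cfg.ct_b * math.log2(max(x, 1e-6))
        for rep in range(1, 4):
            ct = ct0 + (ct_noise * rng.standard_normal() if ct_noise > 0 else 0.0)
            rows.append((sample, gene, rep, round(float(ct), 4), is_ref, assay))

    for sample in truth.samples:
        add(sample, "U6", 500.0, True, "mirna")
        add(sample, "Ubiquitin", 500.0, True, "gene")
        for m in panel_mirnas:
            add(sample, m.mirna_id, m.sample_abundance[sample], False, "mirna")
        for g in panel_genes:
            add(sample, g, float(expr.loc[g, sample]), False, "gene")
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "replicate", "ct", "is_reference", "assay"]
    )


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path: Path, reads: list[tuple[str, list[int]]], sample: str) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            q = "".join(chr(33 + min(qv, 41)) for qv in qual)
            fh.write(f"@{sample}_read{i+1:06d}\n{seq}\n+\n{q}\n")


def simulate(cfg: SyntheticConfig, outdir: str | Path) -> TruthTable:
    """Generate the full synthetic dataset under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    genome = make_genome(cfg)
    reads = simulate_reads(cfg, genome)
    bundle = simulate_expression(cfg, genome)
    truth = genome.truth

    _write_fasta(outdir / "genome.fasta", genome.chroms)
    _write_fasta(outdir / "reference_mirnas.fasta", genome.reference)
    _write_fasta(outdir / "transcripts.fasta", bundle.transcripts)
    with open(outdir / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genome.features.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.source}\t{r.type}\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{r.attr}\n"
            )
    for sample in truth.samples:
        write_fastq(outdir / "reads" / f"{sample}.fastq", reads[sample], sample)
    bundle.expression.rename_axis("gene_id").to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
    bundle.tf_table.to_csv(outdir / "tf_table.tsv", sep="\t", index=False)
    bundle.pathway_map.to_csv(outdir / "pathway_map.tsv", sep="\t", index=False)
    bundle.ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    return truth
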