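"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SyntheticConfig", "RunConfig", "validate_config"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic reaction-wood experiment.

    Defaults mirror the real study's shape: 3 tissues (normal, tension and
    opposite wood) x 3 biological replicates, 12 novel miRNAs carrying 39
    planted target pairs of which 21 land on transcription-factor genes, and
    4-fold planted abundance effects.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 60_000
    n_known_mirnas: int = 8
    n_novel_mirnas: int = 12
    n_genes: int = 200
    n_tfs: int = 30
    n_samples_per_tissue: int = 3
    tissues: tuple[str, ...] = ("NW", "TW", "OW")
    depth: int = 20_000
    de_fold: float = 4.0
    noise_sd: float = 0.25  # sd of log2 replicate noise on miRNA abundance
    target_r: float = 0.95  # planted |Pearson r| for correlation edges
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    read_len: int = 50
    background_frac: float = 0.10
    degrade_frac: float = 0.05  # reads with a decayed 3' quality tail
    n_base_frac: float = 0.02  # reads with >10% N bases
    short_frac: float = 0.02  # background reads with a <18 nt insert
    loop_len: int = 6
    max_bulges: int = 2
    n_target_pairs: int = 39
    n_tf_targets: int = 21
    n_downstream_per_tf: int = 3
    transcript_len: int = 500
    enriched_pathway: str = "ko00940"
    other_pathways: tuple[str, ...] = ("ko00360", "ko00620", "ko00061", "ko00500", "ko04075")
    ct_a: float = 35.0
    ct_b: float = 1.0
    u_start_frac: float = 0.70
    mature_len_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.15, 21: 0.50, 22: 0.15, 24: 0.20}
    )

    @property
    def samples(self) -> list[str]:
        return [f"{t}{i}" for t in self.tissues for i in range(1, self.n_samples_per_tissue + 1)]

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.de_fold < 2:
            raise ValueError("de_fold must be >= 2")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        if not 0.8 <= self.target_r <= 1.0:
            raise ValueError("target_r must be in [0.8, 1] so planted correlations pass -0.8")
        if self.n_tf_targets > self.n_target_pairs:
            raise ValueError("n_tf_targets cannot exceed n_target_pairs")
        if self.n_target_pairs + self.n_tf_targets * self.n_downstream_per_tf > self.n_genes:
            raise ValueError("n_genes too small for planted targets and downstream genes")
        if set(self.adapter_seq) - set("ACGT"):
            raise ValueError("adapter_seq must be a DNA string")

    def zero_noise(self) -> "SyntheticConfig":
        """A copy with every stochastic nuisance switched off (planted
        structure only); the recoverability tests run under this."""
        return replace(
            self,
            noise_sd=0.0,
            target_r=1.0,
            background_frac=0.0,
            degrade_frac=0.0,
            n_base_frac=0.0,
            short_frac=0.0,
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["other_pathways"] = list(self.other_pathways)
        d["mature_len_weights"] = {str(k): v for k, v in self.mature_len_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        d = dict(d)
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        if "other_pathways" in d:
            d["other_pathways"] = tuple(d["other_pathways"])
        if "mature_len_weights" in d:
            d["mature_len_weights"] = {int(k): v for k, v in d["mature_len_weights"].items()}
        return cls(**d)


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs: input paths and the
    thresholds of every stage (defaults are the study's printed values)."""

    # inputs
    outdir: str = "run_out"
    genome_fasta: str = ""
    annotation_gff: str = ""
    reference_fasta: str = ""
    fastq_dir: str = ""
    expression_tsv: str = ""
    transcripts_fasta: str = ""
    tf_table_tsv: str = ""
    pathway_map_tsv: str = ""
    ct_table_tsv: str = ""  # optional
    samples: tuple[str, ...] = ()
    tissues: tuple[str, ...] = ("NW", "TW", "OW")
    seed: int = 0
    # read cleaning
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 30
    max_n_frac: float = 0.10
    min_tail_q: int = 20
    tail_window: int = 3
    # discovery
    flank: int = 80
    min_novel_count: int = 2
    family_max_distance: int = 3
    # differential abundance
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    pseudocount: float = 1.0
    # targets
    expectation_cutoff: float = 3.0
    # network
    r_max: float = -0.8
    corr_p_max: float = 0.05
    tf_r_min: float = 0.8
    tf_p_max: float = 0.05
    # qpcr
    calibrator_tissue: str = "NW"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["samples"] = list(self.samples)
        d["tissues"] = list(self.tissues)
        Path(path).write_text(yaml.safe_dump({"mirwoodnet_run": 1, **d}, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.pop("mirwoodnet_run", None)
        d["samples"] = tuple(d.get("samples", ()))
        d["tissues"] = tuple(d.get("tissues", ()))
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Range-check a run configuration; returns problems, raises nothing."""
    problems: list[str] = []
    if not (-1.0 <= config.r_max < 0.0):
        problems.append(f"r_max must be in [-1, 0), got {config.r_max}")
    if not (0.0 < config.corr_p_max <= 1.0):
        problems.append(f"corr_p_max must be in (0, 1], got {config.corr_p_max}")
    if not (0.0 < config.tf_r_min <= 1.0):
        problems.append(f"tf_r_min must be in (0, 1], got {config.tf_r_min}")
    if config.expectation_cutoff < 0:
        problems.append(f"expectation_cutoff must be >= 0, got {config.expectation_cutoff}")
    if config.fc_threshold < 1:
        problems.append(f"fc_threshold must be >= 1, got {config.fc_threshold}")
    if not (0.0 < config.p_threshold <= 1.0):
        problems.append(f"p_threshold must be in (0, 1], got {config.p_threshold}")
    if config.min_len < 1 or config.max_len < config.min_len:
        problems.append("read length window invalid")
    if set(config.adapter_seq) - set("ACGT"):
        problems.append("adapter_seq must be a DNA string")
    for name in (
        "genome_fasta",
        "annotation_gff",
        "reference_fasta",
        "fastq_dir",
        "expression_tsv",
        "transcripts_fasta",
        "tf_table_tsv",
        "pathway_map_tsv",
    ):
        p = getattr(config, name)
        if not p:
            problems.append(f"{name} not set")
        elif not Path(p).exists():
            problems.append(f"{name}: {p} does not exist")
    if config.ct_table_tsv and not Path(config.ct_table_tsv).exists():
        problems.append(f"ct_table_tsv: {config.ct_table_tsv} does not exist")
    if config.calibrator_tissue not in config.tissues:
        problems.append(f"calibrator tissue {config.calibrator_tissue!r} not among tissues")
    return problems
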