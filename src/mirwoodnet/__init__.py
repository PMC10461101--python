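"""mirwoodnet: small-RNA to miRNA-TF-mRNA network analysis with planted truth."""

from __future__ import annotations

from pathlib import Path

from .config import RunConfig, SyntheticConfig, validate_config
from .pipeline import RunResult, run_all
from .synth import TruthTable, simulate

__version__ = "0.1.0"

__all__ = [
    "RunConfig",
    "SyntheticConfig",
    "TruthTable",
    "RunResult",
    "run_all",
    "simulate",
    "validate_config",
    "simulate_and_configure",
]


def simulate_and_configure(
    cfg: SyntheticConfig, datadir: str | Path, outdir: str | Path | None = None
) -> tuple[TruthTable, RunConfig]:
    """Generate a synthetic dataset and the matching run configuration."""
    datadir = Path(datadir)
    truth = simulate(cfg, datadir)
    run_cfg = RunConfig(
        outdir=str(outdir if outdir is not None else datadir / "run"),
        genome_fasta=str(datadir / "genome.fasta"),
        annotation_gff=str(datadir / "annotation.gff3"),
        reference_fasta=str(datadir / "reference_mirnas.fasta"),
        fastq_dir=str(datadir / "reads"),
        expression_tsv=str(datadir / "expression.tsv"),
        transcripts_fasta=str(datadir / "transcripts.fasta"),
        tf_table_tsv=str(datadir / "tf_table.tsv"),
        pathway_map_tsv=str(datadir / "pathway_map.tsv"),
        ct_table_tsv=str(datadir / "ct_table.tsv"),
        samples=tuple(truth.samples),
        tissues=tuple(cfg.tissues),
        seed=cfg.seed,
        adapter_seq=cfg.adapter_seq,
        calibrator_tissue=cfg.tissues[0],
    )
    return truth, run_cfg
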