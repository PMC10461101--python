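"""End-to-end orchestration: clean -> map -> discover -> de -> targets ->
network -> enrich (-> qpcr), from a single :class:`RunConfig`.

Every stage writes its table under the output directory and logs its record
counts into a machine-readable run report (JSON) whose checksums make
determinism checkable: two runs with the same config and seed must produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import discovery, io, network, qpcr, reads, targets
from .config import RunConfig, validate_config

__all__ = ["RunResult", "run_all"]

log = logging.getLogger("mirwoodnet")


@dataclass
class RunResult:
    config: RunConfig
    stats: list[reads.CleanStats]
    catalog: reads.TagCatalog
    masked_catalog: reads.TagCatalog
    records: list[discovery.MirnaRecord]
    abund: ab.AbundanceMatrix
    de: pd.DataFrame
    de_summary: pd.DataFrame
    hits: pd.DataFrame
    validated: pd.DataFrame
    net: network.TripartiteNetwork
    enrichment: pd.DataFrame
    qpcr_summary: pd.DataFrame | None
    report: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sample_tissues(samples: list[str], tissues: tuple[str, ...]) -> dict[str, str]:
    out = {}
    for s in samples:
        match = [t for t in tissues if s.startswith(t)]
        if not match:
            raise ValueError(f"sample {s!r} does not start with a tissue label {tissues}")
        out[s] = max(match, key=len)
    return out


def _hits_frame(hit_list: list[targets.TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": h.mirna_id,
                "transcript_id": h.transcript_id,
                "expectation": h.expectation,
                "site_start": h.site_start,
                "site_end": h.site_end,
                "cleavage_pos": h.cleavage_pos,
                "mirna_aln": h.alignment.mirna_aln,
                "site_aln": h.alignment.site_aln,
            }
            for h in hit_list
        ],
        columns=[
            "mirna_id",
            "transcript_id",
            "expectation",
            "site_start",
            "site_end",
            "cleavage_pos",
            "mirna_aln",
            "site_aln",
        ],
    )


def run_all(config: RunConfig) -> RunResult:
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "parameters": {}}
    samples = list(config.samples)
    tissue_of = _sample_tissues(samples, config.tissues)

    # --- clean ---------------------------------------------------------
    genome = io.read_fasta(config.genome_fasta)
    clean_sets: dict[str, reads.ReadSet] = {}
    stats: list[reads.CleanStats] = []
    for s in samples:
        raw = reads.ReadSet(sample_id=s, reads=io.read_fastq(Path(config.fastq_dir) / f"{s}.fastq"))
        cs, st = reads.clean_reads(
            raw,
            config.adapter_seq,
            min_len=config.min_len,
            max_len=config.max_len,
            max_n_frac=config.max_n_frac,
            min_tail_q=config.min_tail_q,
            tail_window=config.tail_window,
        )
        clean_sets[s] = cs
        stats.append(st)
    log.info("clean: %d samples", len(samples))
    report["stages"].append({"stage": "clean", "samples": len(samples)})

    # --- map -----------------------------------------------------------
    catalog, mapped = reads.collapse_and_map(clean_sets, genome)
    for st in stats:
        st.mapped_srna = mapped[st.sample_id]
        st.compute_ratio()
    features = io.read_gff3(config.annotation_gff)
    mask = features[features["type"].isin(reads.MASKED_FEATURE_TYPES)]
    masked_catalog = reads.mask_annotated(catalog, mask)
    report["stages"].append(
        {
            "stage": "map",
            "tags": len(catalog.tags),
            "tags_after_masking": len(masked_catalog.tags),
        }
    )
    stats_df = pd.DataFrame(
        [
            {
                "Sample": st.sample_id,
                "Raw reads": st.raw_reads,
                "Clean reads": st.clean_reads,
                "Total sRNA": st.total_srna,
                "Mapped sRNA": st.mapped_srna,
                "Mapping ratio (%)": st.mapping_ratio,
            }
            for st in stats
        ]
    )
    stats_df.to_csv(outdir / "clean_stats.tsv", sep="\t", index=False)
    masked_catalog.counts.to_csv(outdir / "tag_catalog.tsv", sep="\t")
    reads.length_profile(masked_catalog, config.min_len, config.max_len).to_csv(
        outdir / "length_profile.tsv", sep="\t", header=["fraction"]
    )
    reads.first_base_profile(masked_catalog, config.min_len, config.max_len).to_csv(
        outdir / "first_base_profile.tsv", sep="\t"
    )

    # --- discover ------------------------------------------------------
    reference = io.read_fasta(config.reference_fasta)
    known = discovery.match_known(masked_catalog, reference)
    novel = discovery.call_novel(
        masked_catalog,
        genome,
        known,
        flank=config.flank,
        min_count=config.min_novel_count,
    )
    for rec in novel:
        rec.family = discovery.assign_family(rec, reference, config.family_max_distance)
    records = known + novel
    if len({r.mirna_id for r in records}) != len(records):
        raise ValueError("duplicate miRNA IDs after discovery")
    report["stages"].append({"stage": "discover", "known": len(known), "novel": len(novel)})
    mirna_rows = []
    for r in records:
        loc = f"{r.locus[0]}:{r.locus[1]}:{r.locus[2]}" if r.locus else ""
        mirna_rows.append(
            {"mirna_id": r.mirna_id, "status": r.status, "family": r.family or "",
             "mature_seq": r.mature_seq, "locus": loc}
        )
    pd.DataFrame(mirna_rows).to_csv(outdir / "mirna_table.tsv", sep="\t", index=False)
    hp_rows = [
        {
            "mirna_id": r.mirna_id,
            "window": f"{r.precursor.chrom}:{r.precursor.start}-{r.precursor.end}:{r.precursor.strand}",
            "structure": r.precursor.structure,
            "pair_count": r.precursor.pair_count,
            "verdict": r.precursor.verdict,
        }
        for r in novel
        if r.precursor
    ]
    pd.DataFrame(hp_rows, columns=["mirna_id", "window", "structure", "pair_count", "verdict"]).to_csv(
        outdir / "hairpin_report.tsv", sep="\t", index=False
    )

    # --- differential abundance ---------------------------------------
    counts = pd.DataFrame(
        [[r.counts.get(s, 0) for s in samples] for r in records],
        index=[r.mirna_id for r in records],
        columns=samples,
    )
    counts.index.name = "mirna_id"
    totals = pd.Series({st.sample_id: st.mapped_srna for st in stats})
    abund = ab.normalize(counts, totals)
    tissues = list(config.tissues)
    contrasts = [(a, b) for i, a in enumerate(tissues) for b in tissues[i + 1 :]]
    de = ab.de_table(
        abund,
        tissue_of,
        contrasts,
        pseudocount=config.pseudocount,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
    )
    desum = ab.de_summary(de)
    report["stages"].append(
        {"stage": "de", "tests": len(de), "significant": int(de["significant"].sum())}
    )
    abund.values.round(4).to_csv(outdir / "abundance.tsv", sep="\t")
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
    desum.to_csv(outdir / "de_summary.tsv", sep="\t", index=False)

    # --- targets -------------------------------------------------------
    transcripts = io.read_fasta(config.transcripts_fasta)
    mirna_seqs = {r.mirna_id: r.mature_seq for r in records}
    _, best_hits = targets.predict_targets(mirna_seqs, transcripts, cutoff=config.expectation_cutoff)
    hits = _hits_frame(best_hits)
    report["stages"].append({"stage": "targets", "pairs": len(hits)})
    hits.to_csv(outdir / "target_hits.tsv", sep="\t", index=False)

    # --- network -------------------------------------------------------
    expr = io.read_expression(config.expression_tsv)
    validated = network.anticorrelation_filter(
        hits, abund.values, expr, r_max=config.r_max, p_max=config.corr_p_max
    )
    tf_table = pd.read_csv(config.tf_table_tsv, sep="\t")
    validated_genes = set(validated.loc[validated["validated"], "transcript_id"])
    tf_ids = sorted(validated_genes & set(tf_table["gene_id"]))
    tf_edges = network.tf_layer(tf_ids, expr, r_min=config.tf_r_min, p_max=config.tf_p_max)
    net = network.build_network(validated, tf_edges, tf_table)
    report["stages"].append(
        {
            "stage": "network",
            "validated_pairs": int(validated["validated"].sum()),
            "tf_edges": len(tf_edges),
            "nodes": net.graph.number_of_nodes(),
            "edges": net.graph.number_of_edges(),
        }
    )
    validated.to_csv(outdir / "validated_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    net.write_sif(outdir / "network.sif")
    net.write_graphml(outdir / "network.graphml")
    net.node_table().to_csv(outdir / "node_attributes.tsv", sep="\t", index=False)

    # --- enrichment ----------------------------------------------------
    pathway_map = pd.read_csv(config.pathway_map_tsv, sep="\t")
    network_genes = {n for n, d in net.graph.nodes(data=True) if d["type"] in ("TF", "gene")}
    background = set(expr.index)
    enrichment = network.enrich(network_genes & background, background, pathway_map)
    report["stages"].append({"stage": "enrich", "pathways": len(enrichment)})
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    # --- qpcr (optional) ----------------------------------------------
    qpcr_summary = None
    if config.ct_table_tsv:
        ct = pd.read_csv(config.ct_table_tsv, sep="\t")
        rel = qpcr.relative_expression(ct, tissue_of, calibrator=config.calibrator_tissue)
        qpcr_summary = qpcr.summarize(rel)
        rel.to_csv(outdir / "qpcr_relative.tsv", sep="\t", index=False, float_format="%.6g")
        qpcr_summary.to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False, float_format="%.6g")
        report["stages"].append({"stage": "qpcr", "assays": int(rel["gene_id"].nunique())})

    report["parameters"] = {
        k: v for k, v in vars(config).items() if isinstance(v, (int, float, str, bool))
    }
    report["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.suffix in (".tsv", ".sif", ".graphml")
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return RunResult(
        config=config,
        stats=stats,
        catalog=catalog,
        masked_catalog=masked_catalog,
        records=records,
        abund=abund,
        de=de,
        de_summary=desum,
        hits=hits,
        validated=validated,
        net=net,
        enrichment=enrichment,
        qpcr_summary=qpcr_summary,
        report=report,
    )
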