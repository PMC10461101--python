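#!/usr/bin/env python
"""qPCR validation: does 2^-ddCt agree with the sequencing-based calls?

For every panel miRNA, compares the qPCR log2 fold-change (TW vs the NW
calibrator) against the pipeline's DE log2 fold-change and reports sign
concordance, the study's validation criterion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mirwoodnet.synth import TruthTable

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"
TABLES = RESULTS / "tables"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    run = SCRATCH / "run_zero"
    truth = TruthTable.from_json((SCRATCH / "data_zero" / "truth.json").read_text())
    qp = pd.read_csv(run / "qpcr_summary.tsv", sep="\t")
    de = pd.read_csv(run / "de_table.tsv", sep="\t")
    mirnas = pd.read_csv(run / "mirna_table.tsv", sep="\t")
    called_id = dict(zip(mirnas["mature_seq"], mirnas["mirna_id"]))
    seq_of = {m.mirna_id: m.mature_seq for m in truth.mirnas}

    rows = []
    for truth_id in truth.qpcr_panel["mirnas"]:
        pid = called_id.get(seq_of[truth_id])
        qrow = qp[(qp["gene_id"] == truth_id) & (qp["tissue"] == "TW")]
        drow = de[(de["mirna_id"] == pid) & (de["contrast"] == "NW:TW")]
        if not len(qrow) or not len(drow):
            continue
        q_fc = float(qrow["log2_fc"].iloc[0])  # TW relative to NW
        s_fc = -float(drow["log2_fc"].iloc[0])  # de table is NW-over-TW
        rows.append(
            {
                "mirna": truth_id,
                "qpcr_log2fc_TW_vs_NW": round(q_fc, 3),
                "seq_log2fc_TW_vs_NW": round(s_fc, 3),
                "concordant": bool(np.sign(q_fc) == np.sign(s_fc)) or abs(q_fc) < 0.1,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(TABLES / "qpcr_concordance.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nconcordant: {int(table['concordant'].sum())}/{len(table)} panel miRNAs")


if __name__ == "__main__":
    main()
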