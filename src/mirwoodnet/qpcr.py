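"""Relative expression from qPCR Ct tables via the 2^-ddCt method.

Each target Ct is first normalized to the reference gene of its assay group
(dCt = Ct_target - Ct_reference, per sample and technical replicate), then
to a calibrator condition (ddCt = dCt - dCt_calibrator); relative expression
is efficiency^-ddCt with efficiency fixed at 2.0 by default. Technical
replicates are averaged on the linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["delta_delta_ct", "relative_expression", "summarize"]


def delta_delta_ct(
    target_ct: float,
    ref_ct: float,
    calib_target_ct: float,
    calib_ref_ct: float,
    efficiency: float = 2.0,
) -> float:
    """efficiency^-((target - ref) - (calib_target - calib_ref))."""
    for v in (target_ct, ref_ct, calib_target_ct, calib_ref_ct):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_ct - ref_ct) - (calib_target_ct - calib_ref_ct)
    return float(efficiency**-ddct)


def _check_ct(ct: pd.DataFrame) -> None:
    required = {"sample_id", "gene_id", "replicate", "ct", "is_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def relative_expression(
    ct: pd.DataFrame,
    sample_tissues: dict[str, str],
    calibrator: str = "NW",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-(gene, sample, replicate) relative expression, 2^-ddCt.

    Normalization groups are the values of an ``assay`` column when present
    (one reference gene each), otherwise the whole table. The calibrator
    dCt for each gene is the mean dCt over all samples of the calibrator
    tissue.
    """
    _check_ct(ct)
    groups = ct.groupby("assay") if "assay" in ct.columns else [("all", ct)]
    out = []
    for assay, grp in groups:
        ref_genes = sorted(grp.loc[grp["is_reference"], "gene_id"].unique())
        if len(ref_genes) != 1:
            raise ValueError(
                f"normalization group {assay!r} needs exactly one reference gene, got {ref_genes}"
            )
        ref = grp[grp["gene_id"] == ref_genes[0]].set_index(["sample_id", "replicate"])["ct"]
        targets = grp[~grp["is_reference"]]
        dct = targets.copy()
        dct["dct"] = [
            row.ct - float(ref.loc[(row.sample_id, row.replicate)])
            for row in targets.itertuples(index=False)
        ]
        calib_samples = [s for s, t in sample_tissues.items() if t == calibrator]
        if not calib_samples:
            raise ValueError(f"no samples for calibrator tissue {calibrator!r}")
        calib = dct[dct["sample_id"].isin(calib_samples)].groupby("gene_id")["dct"].mean()
        for row in dct.itertuples(index=False):
            rel = float(efficiency ** -(row.dct - float(calib.loc[row.gene_id])))
            out.append(
                {
                    "assay": assay,
                    "gene_id": row.gene_id,
                    "sample_id": row.sample_id,
                    "tissue": sample_tissues.get(row.sample_id, ""),
                    "replicate": row.replicate,
                    "relative_expression": rel,
                }
            )
    return pd.DataFrame(out)


@dataclass
class _Summary:
    mean: float
    se: float | None
    log2_fc: float


def summarize(rel: pd.DataFrame, by: tuple[str, ...] = ("gene_id", "tissue")) -> pd.DataFrame:
    """Mean +/- standard error of relative expression per group.

    Replicates are averaged on the linear 2^-ddCt scale; the log2
    fold-change of the group mean is reported alongside. A single-replicate
    group gets a NaN standard error and is flagged.
    """
    rows = []
    for key, grp in rel.groupby(list(by), sort=True):
        vals = grp["relative_expression"].to_numpy(dtype=float)
        k = len(vals)
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
        rows.append(
            dict(
                zip(by, key if isinstance(key, tuple) else (key,)),
                n=k,
                mean=mean,
                se=se,
                log2_fc=float(np.log2(mean)) if mean > 0 else float("-inf"),
                single_replicate=k < 2,
            )
        )
    return pd.DataFrame(rows)
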