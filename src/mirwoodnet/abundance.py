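"""miRNA abundance normalization and differential-abundance testing.

Abundance is normalized as reads per million mapped reads:
``count / total_mapped * 1e6``. Differential abundance between two tissues
is called on the study's thresholds (|fold change| >= 2 and P <= 0.05), with
the fold change computed on pseudocounted group means and the P value from a
two-sided Welch t-test on log2(abundance + pseudocount); both-groups-constant
degenerate cases resolve to P = 0 (disjoint constants) or P = 1 (equal).
Raw P drives the significance call, mirroring the study's raw-P threshold;
Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AbundanceMatrix", "DEResult", "normalize", "de_test", "de_table", "de_summary"]


@dataclass
class AbundanceMatrix:
    values: pd.DataFrame  # miRNA x sample, reads per million
    totals: pd.Series  # per-sample mapped read counts


@dataclass
class DEResult:
    mirna_id: str
    contrast: tuple[str, str]
    log2_fc: float
    p_value: float
    direction: str  # up-in-<A> | up-in-<B> | flat
    significant: bool


def normalize(counts: pd.DataFrame, totals: pd.Series) -> AbundanceMatrix:
    """Reads-per-million normalization; no pseudocount at this stage."""
    totals = totals.reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals[totals.isna()].index)
        raise ValueError(f"missing totals for samples: {missing}")
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero mapped-read total for sample {zero.index[0]!r}")
    return AbundanceMatrix(values=counts / totals * 1e6, totals=totals.astype(int))


def de_test(
    a: np.ndarray,
    b: np.ndarray,
    contrast: tuple[str, str] = ("A", "B"),
    mirna_id: str = "",
    pseudocount: float = 1.0,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> DEResult:
    """Welch t-test between two replicate groups of normalized abundances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    fc = (a.mean() + pseudocount) / (b.mean() + pseudocount)
    log2_fc = float(np.log2(fc))
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    if np.ptp(la) == 0 and np.ptp(lb) == 0:  # both groups constant
        p = 1.0 if la[0] == lb[0] else 0.0
    else:
        p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
    significant = (fc >= fc_threshold or fc <= 1.0 / fc_threshold) and p <= p_threshold
    if log2_fc > 0:
        direction = f"up-in-{contrast[0]}"
    elif log2_fc < 0:
        direction = f"up-in-{contrast[1]}"
    else:
        direction = "flat"
    return DEResult(
        mirna_id=mirna_id,
        contrast=contrast,
        log2_fc=log2_fc,
        p_value=p,
        direction=direction,
        significant=significant,
    )


def de_table(
    abund: AbundanceMatrix,
    sample_tissues: dict[str, str],
    contrasts: list[tuple[str, str]],
    pseudocount: float = 1.0,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run every contrast over every miRNA; BH correction within contrast."""
    rows = []
    for t_a, t_b in contrasts:
        cols_a = [s for s, t in sample_tissues.items() if t == t_a]
        cols_b = [s for s, t in sample_tissues.items() if t == t_b]
        res = [
            de_test(
                abund.values.loc[mid, cols_a].to_numpy(),
                abund.values.loc[mid, cols_b].to_numpy(),
                contrast=(t_a, t_b),
                mirna_id=mid,
                pseudocount=pseudocount,
                fc_threshold=fc_threshold,
                p_threshold=p_threshold,
            )
            for mid in abund.values.index
        ]
        q = multipletests([r.p_value for r in res], method="fdr_bh")[1] if res else []
        for r, qv in zip(res, q):
            rows.append(
                {
                    "mirna_id": r.mirna_id,
                    "contrast": f"{t_a}:{t_b}",
                    "log2_fc": r.log2_fc,
                    "p": r.p_value,
                    "q": float(qv),
                    "direction": r.direction,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)


def de_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast significant counts, split by direction."""
    rows = []
    for contrast, grp in table.groupby("contrast", sort=True):
        sig = grp[grp["significant"]]
        t_a, t_b = contrast.split(":")
        rows.append(
            {
                "contrast": contrast,
                "significant": len(sig),
                f"up_in_first": int((sig["direction"] == f"up-in-{t_a}").sum()),
                f"up_in_second": int((sig["direction"] == f"up-in-{t_b}").sum()),
            }
        )
    return pd.DataFrame(rows)
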