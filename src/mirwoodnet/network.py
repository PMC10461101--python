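"""Anti-correlation target validation, TF layer, tripartite network, enrichment.

A predicted target is *validated* when its transcript levels are strongly
anti-correlated with its miRNA's abundance across the nine samples
(Pearson r <= -0.8 and P <= 0.05). Transcription-factor genes among the
validated targets get a co-expression layer (|r| >= 0.8, P <= 0.05 against
all other genes), and the three layers are assembled into a typed
miRNA -> TF/gene -> co-expressed-gene network. Pathway membership of network
genes is scored with a hypergeometric upper-tail test plus BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationEdge",
    "TripartiteNetwork",
    "pearson_r",
    "pearson_p",
    "anticorrelation_filter",
    "tf_layer",
    "build_network",
    "enrich",
]


@dataclass
class CorrelationEdge:
    source_id: str
    target_id: str
    r: float
    p_value: float
    n: int
    layer: str  # mirna-target | tf-coexpression


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def pearson_p(r: float, n: int) -> float:
    """Two-sided P for a Pearson correlation via the t transform.

    t = r*sqrt((n-2)/(1-r^2)) against t with n-2 degrees of freedom;
    |r| = 1 resolves to P = 0 by convention.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"invalid correlation {r}")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def anticorrelation_filter(
    hits: pd.DataFrame,
    mirna_abund: pd.DataFrame,
    expr: pd.DataFrame,
    r_max: float = -0.8,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Keep predicted (miRNA, transcript) pairs with r <= r_max and p <= p_max.

    ``hits`` needs columns mirna_id/transcript_id; sample columns of the two
    matrices must agree as sets (expression is re-ordered to the miRNA
    matrix). Degenerate (zero-variance) pairs are skipped and recorded with
    NaN statistics.
    """
    if set(mirna_abund.columns) != set(expr.columns):
        raise ValueError("sample columns of miRNA and expression matrices differ")
    expr = expr[mirna_abund.columns]
    n = mirna_abund.shape[1]
    rows = []
    for rec in hits.itertuples(index=False):
        mid, gid = rec.mirna_id, rec.transcript_id
        if mid not in mirna_abund.index or gid not in expr.index:
            continue
        try:
            r = pearson_r(mirna_abund.loc[mid].to_numpy(), expr.loc[gid].to_numpy())
            p = pearson_p(r, n)
        except ValueError:
            rows.append({"mirna_id": mid, "transcript_id": gid, "r": np.nan, "p": np.nan, "validated": False})
            continue
        rows.append(
            {
                "mirna_id": mid,
                "transcript_id": gid,
                "r": r,
                "p": p,
                "validated": bool(r <= r_max and p <= p_max),
            }
        )
    return pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "r", "p", "validated"])


def tf_layer(
    tf_ids: list[str],
    expr: pd.DataFrame,
    r_min: float = 0.8,
    p_max: float = 0.05,
) -> list[CorrelationEdge]:
    """TF -> gene co-expression edges with |r| >= r_min and p <= p_max.

    Self-edges are excluded; zero-variance genes are skipped. The sign of r
    is retained on the edge.
    """
    missing = [t for t in tf_ids if t not in expr.index]
    if missing:
        raise ValueError(f"unknown TF ids: {missing}")
    n = expr.shape[1]
    mat = expr.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    genes = list(expr.index)
    edges: list[CorrelationEdge] = []
    for tf in sorted(tf_ids):
        ti = genes.index(tf)
        if sd[ti] == 0:
            continue
        x = mat[ti]
        xc = x - x.mean()
        yc = mat - mat.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (yc @ xc) / np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
        for gi, gene in enumerate(genes):
            if gene == tf or sd[gi] == 0 or not np.isfinite(r[gi]):
                continue
            if abs(r[gi]) >= r_min:
                p = pearson_p(float(r[gi]), n)
                if p <= p_max:
                    edges.append(
                        CorrelationEdge(
                            source_id=tf,
                            target_id=gene,
                            r=float(r[gi]),
                            p_value=p,
                            n=n,
                            layer="tf-coexpression",
                        )
                    )
    return edges


@dataclass
class TripartiteNetwork:
    graph: nx.DiGraph

    def node_table(self) -> pd.DataFrame:
        rows = [{"id": n, "type": d["type"]} for n, d in sorted(self.graph.nodes(data=True))]
        return pd.DataFrame(rows, columns=["id", "type"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "interaction": d["interaction"],
                "r": d["r"],
                "p": d["p"],
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "interaction", "r", "p"])

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{d['interaction']}\t{v}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(
    validated: pd.DataFrame,
    tf_edges: list[CorrelationEdge],
    tf_table: pd.DataFrame,
) -> TripartiteNetwork:
    """Assemble the typed miRNA-TF-gene network.

    miRNA -> target edges come from the validated (target-predicted and
    anti-correlated) pairs; TF -> gene edges from the co-expression layer.
    Node types resolve through ``tf_table`` (gene_id column). Integrity is
    asserted on build: every edge endpoint must be typed, and every
    miRNA edge must carry its correlation evidence.
    """
    tf_set = set(tf_table["gene_id"])
    g = nx.DiGraph()
    val = validated[validated["validated"]] if "validated" in validated.columns else validated
    for rec in sorted(val.itertuples(index=False), key=lambda r: (r.mirna_id, r.transcript_id)):
        if not np.isfinite(rec.r):
            raise ValueError(f"miRNA edge without correlation evidence: {rec.mirna_id}->{rec.transcript_id}")
        gtype = "TF" if rec.transcript_id in tf_set else "gene"
        g.add_node(rec.mirna_id, type="miRNA")
        g.add_node(rec.transcript_id, type=gtype)
        g.add_edge(
            rec.mirna_id,
            rec.transcript_id,
            interaction="targets",
            r=float(rec.r),
            p=float(rec.p),
        )
    for e in sorted(tf_edges, key=lambda e: (e.source_id, e.target_id)):
        g.add_node(e.source_id, type="TF" if e.source_id in tf_set else "gene")
        if e.target_id not in g:
            g.add_node(e.target_id, type="TF" if e.target_id in tf_set else "gene")
        g.add_edge(e.source_id, e.target_id, interaction="coexpressed", r=e.r, p=e.p_value)
    for u, v in g.edges():
        if u not in g.nodes or v not in g.nodes:  # pragma: no cover - networkx guarantees
            raise ValueError("edge references absent node")
    return TripartiteNetwork(graph=g)


def enrich(
    network_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
    pathway_map: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric pathway over-representation of the network genes.

    For each pathway with K background members, of which k fall in the
    n-gene network drawn from the N-gene background, p = P(X >= k) for
    X ~ Hypergeom(N, K, n); q is BH-adjusted across pathways.
    """
    network = set(network_genes)
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene set")
    if not network <= background:
        raise ValueError("network genes must be a subset of the background")
    pm = pathway_map[pathway_map["gene_id"].isin(background)]
    N = len(background)
    n = len(network)
    rows = []
    for pathway, grp in pm.groupby("pathway_id", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & network)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pathway, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["pathway_id", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values(["p", "pathway_id"], ignore_index=True)
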