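"""Correlation filters, tripartite assembly and hypergeometric enrichment."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirwoodnet.network import (
    CorrelationEdge,
    anticorrelation_filter,
    build_network,
    enrich,
    pearson_p,
    pearson_r,
    tf_layer,
)


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(9, dtype=float)
        assert pearson_r(x, -2 * x + 5) == pytest.approx(-1.0, abs=1e-12)

    def test_closed_form_small_case(self):
        x = np.array([1.0, 2, 3])
        y = np.array([1.0, 2, 4])
        # hand-computed: sum of centered products 3; sums of squares 2 and 14/3
        expected = 3 / math.sqrt(2 * (14 / 3))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.standard_normal((2, 9))
            r_ref, p_ref = stats.pearsonr(x, y)
            assert pearson_r(x, y) == pytest.approx(float(r_ref), abs=1e-12)
            assert pearson_p(pearson_r(x, y), 9) == pytest.approx(float(p_ref), rel=1e-9)

    def test_permutation_mean_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        rs = [pearson_r(x, rng.permutation(x)) for _ in range(1000)]
        assert abs(float(np.mean(rs))) < 0.05

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(9), np.arange(9.0))

    def test_p_properties(self):
        assert pearson_p(0.0, 9) == 1.0
        assert pearson_p(1.0, 9) == 0.0
        ps = [pearson_p(r, 9) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ps == sorted(ps, reverse=True)


class TestAnticorrelationFilter:
    def _data(self):
        samples = [f"s{i}" for i in range(9)]
        x = np.linspace(10, 100, 9)
        mirna = pd.DataFrame([x], index=["m1"], columns=samples)
        expr = pd.DataFrame(
            {
                "perfect": -2 * x + 300,
                "weak": np.array([3.0, 1, 4, 1, 5, 9, 2, 6, 5]),
            }
        ).T
        expr.columns = samples
        hits = pd.DataFrame(
            {"mirna_id": ["m1", "m1"], "transcript_id": ["perfect", "weak"]}
        )
        return hits, mirna, expr

    def test_planted_pair_validated_weak_rejected(self):
        hits, mirna, expr = self._data()
        out = anticorrelation_filter(hits, mirna, expr)
        v = out.set_index("transcript_id")["validated"]
        assert bool(v["perfect"]) and not bool(v["weak"])

    def test_threshold_is_strict(self):
        samples = [f"s{i}" for i in range(9)]
        rng = np.random.default_rng(0)
        # engineer r ~ -0.79: must be rejected at -0.8
        x = np.linspace(0, 1, 9)
        for _ in range(200):
            y = -x + rng.standard_normal(9) * 0.35
            r = pearson_r(x, y)
            if -0.80 < r <= -0.75:
                break
        mirna = pd.DataFrame([x], index=["m1"], columns=samples)
        expr = pd.DataFrame([y], index=["g"], columns=samples)
        hits = pd.DataFrame({"mirna_id": ["m1"], "transcript_id": ["g"]})
        out = anticorrelation_filter(hits, mirna, expr, r_max=-0.8)
        assert not bool(out["validated"].iloc[0])

    def test_monotone_in_thresholds(self):
        hits, mirna, expr = self._data()
        strict = anticorrelation_filter(hits, mirna, expr, r_max=-0.95, p_max=0.01)
        loose = anticorrelation_filter(hits, mirna, expr, r_max=-0.5, p_max=0.2)
        s = set(strict.loc[strict["validated"], "transcript_id"])
        l = set(loose.loc[loose["validated"], "transcript_id"])
        assert s <= l

    def test_sample_mismatch_rejected(self):
        hits, mirna, expr = self._data()
        expr = expr.rename(columns={"s0": "weird"})
        with pytest.raises(ValueError):
            anticorrelation_filter(hits, mirna, expr)


class TestTfLayer:
    def test_planted_coexpression_and_no_self_edges(self):
        samples = [f"s{i}" for i in range(9)]
        x = np.linspace(1, 9, 9)
        expr = pd.DataFrame(
            {"tf1": x, "coex": 3 * x + 1, "anti": -x + 20, "noise": [5, 1, 4, 1, 5, 9, 2, 6, 3]},
        ).T
        expr.columns = samples
        edges = tf_layer(["tf1"], expr)
        ids = {(e.source_id, e.target_id) for e in edges}
        assert ("tf1", "coex") in ids and ("tf1", "anti") in ids
        assert ("tf1", "tf1") not in ids
        signs = {e.target_id: np.sign(e.r) for e in edges}
        assert signs["coex"] == 1 and signs["anti"] == -1

    def test_unknown_tf_errors(self):
        expr = pd.DataFrame(np.ones((2, 9)), index=["a", "b"])
        with pytest.raises(ValueError):
            tf_layer(["nope"], expr)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(9)]
        expr = pd.DataFrame(
            rng.standard_normal((30, 9)), columns=samples,
            index=[f"g{i}" for i in range(30)],
        )
        e1 = tf_layer(["g0"], expr, r_min=0.3)
        e2 = tf_layer(["g0"], expr.iloc[::-1], r_min=0.3)
        key = lambda es: sorted((e.source_id, e.target_id, round(e.r, 12)) for e in es)
        assert key(e1) == key(e2)


class TestBuildNetwork:
    def _validated(self, pairs):
        return pd.DataFrame(
            [
                {"mirna_id": m, "transcript_id": g, "r": -0.9, "p": 0.001, "validated": True}
                for m, g in pairs
            ]
        )

    def test_counting_example(self):
        validated = self._validated([("mir1", "tfA"), ("mir2", "tfB")])
        tf_edges = [
            CorrelationEdge("tfA", "g1", 0.9, 0.001, 9, "tf-coexpression"),
            CorrelationEdge("tfA", "g2", 0.85, 0.003, 9, "tf-coexpression"),
            CorrelationEdge("tfB", "g3", 0.9, 0.001, 9, "tf-coexpression"),
            CorrelationEdge("tfB", "g4", -0.95, 0.001, 9, "tf-coexpression"),
        ]
        tf_table = pd.DataFrame({"gene_id": ["tfA", "tfB"], "family": ["MYB", "C3H"]})
        net = build_network(validated, tf_edges, tf_table)
        assert net.graph.number_of_nodes() == 8
        assert net.graph.number_of_edges() == 6
        types = nx.get_node_attributes(net.graph, "type")
        assert types["mir1"] == "miRNA" and types["tfA"] == "TF" and types["g1"] == "gene"

    def test_empty_network_valid_outputs(self, tmp_path):
        net = build_network(self._validated([]), [], pd.DataFrame({"gene_id": [], "family": []}))
        assert net.graph.number_of_nodes() == 0
        net.write_sif(tmp_path / "e.sif")
        net.write_graphml(tmp_path / "e.graphml")
        assert (tmp_path / "e.sif").read_text() == ""

    def test_graphml_round_trip(self, tmp_path):
        validated = self._validated([("mir1", "tfA")])
        tf_table = pd.DataFrame({"gene_id": ["tfA"], "family": ["MYB"]})
        net = build_network(
            validated,
            [CorrelationEdge("tfA", "g1", 0.9, 0.001, 9, "tf-coexpression")],
            tf_table,
        )
        path = tmp_path / "n.graphml"
        net.write_graphml(path)
        back = nx.read_graphml(path)
        assert sorted(back.nodes) == sorted(net.graph.nodes)
        assert sorted(back.edges) == sorted(net.graph.edges)
        assert nx.get_node_attributes(back, "type") == nx.get_node_attributes(net.graph, "type")


def brute_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) by direct enumeration of draw counts."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestEnrich:
    def _map(self, assignment: dict[str, str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(assignment), "pathway_id": list(assignment.values())}
        )

    def test_everything_in_one_pathway_p_one(self):
        genes = [f"g{i}" for i in range(8)]
        res = enrich(set(genes), set(genes), self._map({g: "P1" for g in genes}))
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_exact_small_case(self):
        background = [f"g{i}" for i in range(20)]
        network = background[:5]
        pm = self._map({g: ("P1" if g in network else "P2") for g in background})
        res = enrich(network, background, pm).set_index("pathway_id")
        assert res.loc["P1", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            N = int(rng.integers(8, 26))
            background = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            network = list(rng.choice(background, n, replace=False))
            members = set(rng.choice(background, K, replace=False))
            pm = self._map({g: ("P1" if g in members else "P0") for g in background})
            res = enrich(network, background, pm).set_index("pathway_id")
            k = len(members & set(network))
            assert res.loc["P1", "p"] == pytest.approx(
                brute_hypergeom_tail(N, K, n, k), rel=1e-10
            )

    def test_network_must_be_subset(self):
        with pytest.raises(ValueError):
            enrich({"x"}, {"a", "b"}, self._map({"a": "P1"}))

    def test_q_at_least_p(self):
        background = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        pm = self._map({g: f"P{int(rng.integers(0, 4))}" for g in background})
        res = enrich(set(background[:10]), background, pm)
        assert (res["q"] >= res["p"] - 1e-15).all()
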