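import numpy as np
import pandas as pd
import pytest

from xtalkflow.hypergraph import (binarize, build_hypergraph_from_triples,
                                  make_training_samples,
                                  personalized_pagerank, score_triples,
                                  spearman_cor)
from xtalkflow.io import PriorNetworks
from xtalkflow.ccc import SignalSet

from conftest import make_expression


def ppr_power_iteration(edges, seed_gene, damping, tol=1e-14):
    """Independent oracle: dense power iteration with restart at the seed,
    dangling mass redirected to the seed."""
    nodes = sorted(set(edges["from"]) | set(edges["to"]))
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    weights = edges["weight"] if "weight" in edges.columns else np.ones(len(edges))
    for u, v, w in zip(edges["from"], edges["to"], weights):
        W[idx[u], idx[v]] = abs(float(w))
    out = W.sum(axis=1)
    e = np.zeros(n)
    e[idx[seed_gene]] = 1.0
    p = np.full(n, 1.0 / n)
    for _ in range(100_000):
        flow = np.zeros(n)
        nz = out > 0
        flow[:] = (p[nz] / out[nz]) @ W[nz]
        dangling = p[~nz].sum()
        new = damping * (flow + dangling * e) + (1 - damping) * e
        if np.abs(new - p).sum() < tol:
            return dict(zip(nodes, new))
        p = new
    return dict(zip(nodes, p))


class TestPPR:
    def test_chain_ordering_matches_power_iteration(self):
        edges = pd.DataFrame({"from": ["seed", "A"], "to": ["A", "B"],
                              "weight": [1.0, 1.0]})
        got = personalized_pagerank(edges, "seed", 0.85)
        want = ppr_power_iteration(edges, "seed", 0.85)
        for g in want:
            assert got[g] == pytest.approx(want[g], abs=1e-9)
        assert got["seed"] > got["A"] > got["B"] > 0

    def test_random_graphs_match_power_iteration(self, rng):
        for trial in range(5):
            n = 8
            rows = [(f"n{i}", f"n{j}", float(rng.uniform(0.1, 2)))
                    for i in range(n) for j in range(n)
                    if i != j and rng.random() < 0.3]
            if not rows:
                continue
            edges = pd.DataFrame(rows, columns=["from", "to", "weight"])
            seed = edges["from"].iloc[0]
            got = personalized_pagerank(edges, seed, 0.85)
            want = ppr_power_iteration(edges, seed, 0.85)
            assert sum(got.values()) == pytest.approx(1.0, abs=1e-9)
            for g in want:
                assert got[g] == pytest.approx(want[g], abs=1e-9)

    def test_unreachable_node_scores_zero(self):
        edges = pd.DataFrame({"from": ["seed", "X"], "to": ["A", "Y"],
                              "weight": [1.0, 1.0]})
        got = personalized_pagerank(edges, "seed", 0.85)
        assert got["Y"] == pytest.approx(0.0, abs=1e-12)
        assert got["X"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_seed_warns_empty(self):
        edges = pd.DataFrame({"from": ["A"], "to": ["B"], "weight": [1.0]})
        assert personalized_pagerank(edges, "zz", 0.85) == {}


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_cor(x, 2 * x + 1) == pytest.approx(1.0)
        assert spearman_cor(x, -x) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks identical except one swap: rho = 1 - 6*2/(4*15) = 0.8
        assert spearman_cor(np.array([1, 2, 3, 4]),
                            np.array([1, 3, 2, 4])) == pytest.approx(0.8)

    def test_zero_variance_defined_as_zero(self):
        assert spearman_cor(np.ones(5), np.arange(5.0)) == 0.0


class TestScoreAndBinarize:
    @pytest.fixture
    def setup(self, rng):
        genes = ["R1", "R2", "TF1", "TF2", "T1", "T2"]
        mat = rng.poisson(5, size=(6, 30)).astype(float) + 1
        expr = make_expression(mat, ["Rcv"] * 30, gene_ids=genes,
                               normalized=mat)
        priors = PriorNetworks(
            pd.DataFrame({"from": ["R1", "R1", "R2"],
                          "to": ["TF1", "TF2", "TF1"], "weight": 1.0}),
            pd.DataFrame({"from": ["TF1", "TF2"], "to": ["T1", "T2"],
                          "weight": 1.0}))
        return expr, priors

    def test_cartesian_scoring(self, setup):
        expr, priors = setup
        df = score_triples(SignalSet(["R1", "R2"]), ["TF1", "TF2"],
                           ["T1", "T2"], priors, expr, "Rcv")
        # R1 reaches both TFs, R2 reaches TF1 (and TF2 via no path)
        assert set(df["Signal"]) == {"R1", "R2"}
        assert (df["S_H"] > 0).all()
        r1 = df[df["Signal"] == "R1"]
        assert len(r1) <= 4 and len(r1) > 0

    def test_top_fraction_count_exact(self, rng):
        n = 100
        df = pd.DataFrame({
            "Signal": [f"S{i%5}" for i in range(n)],
            "SSC": [f"C{i%7}" for i in range(n)],
            "Target": [f"T{i}" for i in range(n)],
            "S_H": rng.uniform(0.01, 1.0, n)})
        hg = binarize(df, top_frac=0.10)
        assert hg.n_edges == 10
        kept_scores = {tuple(e) for e in hg.edges}
        threshold = sorted(df["S_H"], reverse=True)[9]
        for s, c, t, v in df.itertuples(index=False):
            if v > threshold:
                assert (s, c, t) in kept_scores

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({
            "Signal": [f"S{i:02d}" for i in range(20)],
            "SSC": ["C"] * 20, "Target": ["T"] * 20, "S_H": [0.5] * 20})
        hg = binarize(df, top_frac=0.10)
        assert [e[0] for e in hg.edges] == ["S00", "S01"]

    def test_under_ten_triples_all_promoted(self):
        df = pd.DataFrame({"Signal": list("ABCDE"), "SSC": ["C"] * 5,
                           "Target": ["T"] * 5, "S_H": [0.1] * 5})
        assert binarize(df, 0.10).n_edges == 5

    def test_binarize_full_fraction_keeps_all(self, rng):
        df = pd.DataFrame({"Signal": [f"S{i}" for i in range(30)],
                           "SSC": ["C"] * 30, "Target": ["T"] * 30,
                           "S_H": rng.uniform(size=30)})
        assert binarize(df, 1.0).n_edges == 30

    def test_incidence_degrees(self):
        hg = build_hypergraph_from_triples(
            [("S1", "C1", "T1"), ("S1", "C1", "T2")],
            signals=["S1"], sscs=["C1"], targets=["T1", "T2"])
        assert hg.edge_degrees.tolist() == [3.0, 3.0]
        assert hg.node_degrees[hg.node_index("S1")] == 2
        assert hg.node_degrees[hg.node_index("T2")] == 1


class TestTrainingSamples:
    @pytest.fixture
    def scored(self, rng):
        rows = [(f"S{i%4}", f"C{i%5}", f"T{i}", float(rng.uniform(0.01, 1)))
                for i in range(100)]
        return pd.DataFrame(rows, columns=["Signal", "SSC", "Target", "S_H"])

    def test_sizes_and_balance(self, scored):
        hg = binarize(scored, 0.10)
        s = make_training_samples(scored, hg, np.random.default_rng(0))
        assert len(s) == 20 and s.labels.sum() == 10
        assert s.is_train.sum() == 16              # 8 per class
        for cls in (0, 1):
            assert (s.is_train & (s.labels == cls)).sum() == 8

    def test_positives_and_negatives_disjoint(self, scored):
        hg = binarize(scored, 0.10)
        s = make_training_samples(scored, hg, np.random.default_rng(1))
        pos = {t for t, l in zip(s.triples, s.labels) if l == 1}
        neg = {t for t, l in zip(s.triples, s.labels) if l == 0}
        assert pos.isdisjoint(neg)
        assert pos == set(hg.edges)

    def test_seeded_determinism(self, scored):
        hg = binarize(scored, 0.10)
        a = make_training_samples(scored, hg, np.random.default_rng(5))
        b = make_training_samples(scored, hg, np.random.default_rng(5))
        assert a.triples == b.triples
        assert np.array_equal(a.is_train, b.is_train)

    def test_hyperedge_scores_dominate_scored_negatives(self, scored):
        hg = binarize(scored, 0.10)
        lookup = {(s, c, t): v for s, c, t, v in scored.itertuples(index=False)}
        edge_min = min(lookup[e] for e in hg.edges)
        non_edges = [k for k in lookup if k not in set(hg.edges)]
        assert all(lookup[k] <= edge_min for k in non_edges)
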