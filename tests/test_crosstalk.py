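import numpy as np
import pandas as pd
import pytest

from xtalkflow.crosstalk import (activation_index, add_selectivity,
                                 compound_selectivity, fidelity,
                                 pairwise_totals, specificity,
                                 subcluster_receivers, trs_and_totals)

from conftest import make_expression


class TestFidelitySpecificity:
    def test_target_module_normalization(self):
        df = pd.DataFrame({"Signal": ["A", "B", "C"], "SSC": ["X"] * 3,
                           "Target": ["T"] * 3, "PRS": [2.0, 3.0, 5.0]})
        assert fidelity(df, ("A", "X", "T")) == pytest.approx(0.2)
        assert fidelity(df, ("B", "X", "T")) == pytest.approx(0.3)
        assert fidelity(df, ("C", "X", "T")) == pytest.approx(0.5)

    def test_singleton_module_is_one(self):
        df = pd.DataFrame({"Signal": ["A"], "SSC": ["X"], "Target": ["T"],
                           "PRS": [0.7]})
        assert fidelity(df, ("A", "X", "T")) == 1.0
        assert specificity(df, ("A", "X", "T")) == 1.0

    def test_scale_invariance(self, prs_table):
        p = ("S1", "C1", "T1")
        doubled = prs_table.assign(PRS=prs_table["PRS"] * 2)
        assert fidelity(prs_table, p) == pytest.approx(fidelity(doubled, p))
        assert specificity(prs_table, p) == pytest.approx(
            specificity(doubled, p))

    def test_fidelity_and_specificity_can_diverge(self, prs_table):
        # (S1, C1, T1): Fid = 9/10 = 0.9 but Spe = 9/90 = 0.1
        p = ("S1", "C1", "T1")
        assert fidelity(prs_table, p) == pytest.approx(0.9)
        assert specificity(prs_table, p) == pytest.approx(0.1)

    def test_selectivity_columns_sum_to_one_per_module(self, prs_table):
        out = add_selectivity(prs_table)
        for _, grp in out.groupby("Target"):
            assert grp["Fid_target_xmod"].sum() == pytest.approx(1.0, abs=1e-9)
        for _, grp in out.groupby("Signal"):
            assert grp["Spe_signal_xmod"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_sum_module_reported_missing(self):
        df = pd.DataFrame({"Signal": ["A"], "SSC": ["X"], "Target": ["T"],
                           "PRS": [0.0]})
        assert np.isnan(fidelity(df, ("A", "X", "T")))


class TestTotals:
    def test_trs_sums_over_ssc_routes(self):
        df = pd.DataFrame({"Signal": ["A", "A"], "SSC": ["X", "Y"],
                           "Target": ["T", "T"], "PRS": [1.0, 2.0]})
        trs, fid, spe = trs_and_totals(df, "A", "T")
        assert trs == 3.0 and fid == 1.0 and spe == 1.0

    def test_totals_match_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            df = pd.DataFrame({
                "Signal": rng.choice(["A", "B", "C"], 12),
                "SSC": rng.choice(["X", "Y"], 12),
                "Target": rng.choice(["T1", "T2", "T3"], 12),
                "PRS": rng.uniform(0.1, 5, 12)})
            df = df.groupby(["Signal", "SSC", "Target"], as_index=False).sum()
            totals = pairwise_totals(df)
            for r in totals.itertuples(index=False):
                brute = df[(df.Signal == r.Signal)
                           & (df.Target == r.Target)]["PRS"].sum()
                assert r.TRS == pytest.approx(brute)
                denom_f = df[df.Target == r.Target]["PRS"].sum()
                denom_s = df[df.Signal == r.Signal]["PRS"].sum()
                assert r.total_fid == pytest.approx(brute / denom_f)
                assert r.total_spe == pytest.approx(brute / denom_s)
            # per fixed target, total fidelities sum to one
            for _, grp in totals.groupby("Target"):
                assert grp["total_fid"].sum() == pytest.approx(1.0, abs=1e-9)


class TestCompound:
    def test_signal_ssc_module_shares(self):
        df = pd.DataFrame({"Signal": ["A", "A"], "SSC": ["X", "X"],
                           "Target": ["T1", "T2"], "PRS": [1.0, 3.0]})
        shares = compound_selectivity(df, ("Signal", "SSC"))
        assert shares.tolist() == pytest.approx([0.25, 0.75])

    def test_modules_sum_to_one(self, prs_table):
        for shared in (("Signal", "SSC"), ("SSC", "Target")):
            s = compound_selectivity(prs_table, shared)
            sums = prs_table.assign(v=s).groupby(list(shared))["v"].sum()
            assert np.allclose(sums, 1.0)

    def test_invalid_pair_rejected(self, prs_table):
        with pytest.raises(ValueError):
            compound_selectivity(prs_table, ("Signal", "Target"))


class TestACI:
    def _expr(self, x, y):
        mat = np.array([[x], [y]])
        return make_expression(mat, ["A"], gene_ids=["s", "c"],
                               normalized=mat)

    def test_half_saturation(self):
        assert activation_index(self._expr(1.0, 0.5), "s", "c", "c1",
                                k_h=0.5) == pytest.approx(0.5)

    def test_zero_product_zero(self):
        assert activation_index(self._expr(0.0, 3.0), "s", "c", "c1") == 0.0

    def test_strictly_increasing_and_bounded(self):
        vals = [activation_index(self._expr(x, 1.0), "s", "c", "c1")
                for x in (0.1, 0.5, 2.0, 50.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v < 1 for v in vals)


class TestSubclustering:
    def _setup(self, rng, n_half=40):
        genes = [f"M{i}" for i in range(10)] + ["other"]
        hi = rng.uniform(3, 5, size=(10, n_half))
        lo = np.zeros((10, n_half))
        other = rng.uniform(0, 1, size=(1, 2 * n_half))
        mat = np.vstack([np.hstack([hi, lo]), other])
        expr = make_expression(mat, ["Rcv"] * 2 * n_half, gene_ids=genes,
                               normalized=mat)
        totals = pd.DataFrame({
            "Signal": ["S"] * 10, "Target": [f"M{i}" for i in range(10)],
            "TRS": 1.0, "total_fid": 0.5,
            "total_spe": np.linspace(0.9, 0.5, 10)})
        return expr, totals

    def test_recovers_separated_groups(self, rng):
        expr, totals = self._setup(rng)
        labels = subcluster_receivers(expr, "Rcv", "S", totals, seed=0)
        first = labels.iloc[:40]
        second = labels.iloc[40:]
        assert (first == "interacted").all()
        assert (second == "not-interacted").all()

    def test_seeded_determinism(self, rng):
        expr, totals = self._setup(rng)
        a = subcluster_receivers(expr, "Rcv", "S", totals, seed=3)
        b = subcluster_receivers(expr, "Rcv", "S", totals, seed=3)
        assert (a == b).all()

    def test_uniform_weights_match_plain_kmeans(self, rng):
        from sklearn.cluster import KMeans
        expr, totals = self._setup(rng)
        totals["total_spe"] = 0.3            # degenerate equal weights
        labels = subcluster_receivers(expr, "Rcv", "S", totals, seed=1)
        M = expr.normalized[:10].T
        km = KMeans(n_clusters=2, n_init=10, random_state=1).fit_predict(
            M * np.sqrt(0.1))
        # identical partition up to label names
        ours = (labels == "interacted").to_numpy()
        assert (np.array_equal(ours, km == 0)
                or np.array_equal(ours, km == 1))

    def test_too_few_cells_fatal(self, rng):
        expr, totals = self._setup(rng)
        solo = expr.subset(cell_idx=np.array([0]))
        with pytest.raises(ValueError, match="at least 2"):
            subcluster_receivers(solo, "Rcv", "S", totals, seed=0)


class TestSelectivityProperties:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=2,
                    max_size=8),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_shares_sum_to_one_and_scale_invariant(prs_values, scale):
        import pandas as pd
        df = pd.DataFrame({
            "Signal": [f"S{i % 3}" for i in range(len(prs_values))],
            "SSC": "C", "Target": [f"T{i % 2}" for i in range(len(prs_values))],
            "PRS": prs_values})
        df = df.groupby(["Signal", "SSC", "Target"], as_index=False).sum()
        a = add_selectivity(df)
        b = add_selectivity(df.assign(PRS=df["PRS"] * scale))
        for _, grp in a.groupby("Target"):
            assert abs(grp["Fid_target_xmod"].sum() - 1) < 1e-9
        np.testing.assert_allclose(a["Spe_signal_xmod"], b["Spe_signal_xmod"],
                                   rtol=1e-9)
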