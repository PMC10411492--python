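import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import xgrove as xg
from xgrove import conflict as C
from xgrove import trees as T
from xgrove.qc import LocusRecord
from xgrove.substitution import GTRModel, TreeLikelihood, simulate_alignment


@pytest.fixture(scope="module")
def eight_taxon_setup():
    st = T.read_newick("(((A:0.08,B:0.08)100:0.05,(C:0.08,D:0.08)100:0.05)"
                       "100:0.05,(E:0.08,F:0.08)100:0.05,"
                       "(G:0.08,H:0.08)100:0.05);")
    model = GTRModel(freqs=(0.3, 0.2, 0.3, 0.2),
                     rates=(1.5, 3.0, 0.8, 1.2, 4.0, 1.0), alpha=0.8)
    return st, model


class TestDeltaLnl:
    def test_positive_on_generating_topology(self, eight_taxon_setup):
        st, model = eight_taxon_setup
        edges = C.deep_focal_edges(st, 1)
        aln = simulate_alignment(st, model, 800,
                                 rng=np.random.default_rng(10))
        rec = LocusRecord("L1", aln, T.clone(st), "A")
        rows = C.delta_lnl(rec, st, edges, model=model)
        assert rows[0]["status"] == "ok"
        assert rows[0]["delta"] > 0
        assert rows[0]["delta_per_base"] * rows[0]["length_bp"] == \
            pytest.approx(rows[0]["delta"], abs=1e-9)

    def test_antisymmetry_of_pairwise_delta(self, eight_taxon_setup):
        """lnL(ref) - lnL(alt) flips sign exactly when the two topologies
        swap roles."""
        st, model = eight_taxon_setup
        alt = T.nni_neighbors(st)[0]
        aln = simulate_alignment(st, model, 400,
                                 rng=np.random.default_rng(11))

        def opt(tree):
            return TreeLikelihood(aln, tree, model).optimize_branch_lengths(
                max_rounds=6, lnl_tol=1e-3).log_likelihood
        l_ref, l_alt = opt(st), opt(alt)
        assert (l_ref - l_alt) == pytest.approx(-(l_alt - l_ref), abs=0)

    def test_lost_edge_skipped(self, eight_taxon_setup):
        st, model = eight_taxon_setup
        edges = [C.FocalEdge("gone", frozenset({"A", "B", "C"}))]
        aln = simulate_alignment(st, model, 120,
                                 rng=np.random.default_rng(12))
        rec = LocusRecord("L1", aln, T.clone(st), "A")
        rows = C.delta_lnl(rec, st, edges, model=model)
        assert rows[0]["status"] == "edge_lost"

    def test_median_positive_many_loci(self, eight_taxon_setup):
        st, model = eight_taxon_setup
        edges = C.deep_focal_edges(st, 2)
        recs = [LocusRecord(f"L{i}", simulate_alignment(
            st, model, 500, rng=np.random.default_rng(200 + i)),
            T.clone(st), "A") for i in range(12)]
        sig = C.signal_table(recs, st, edges,
                             models={r.id: model for r in recs})
        med = sig[sig.status == "ok"].groupby("edge")[
            "delta_per_base"].median()
        assert (med > 0).all()


class TestBinSignal:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_sum_over_bins_is_total(self):
        rows = [{"locus": f"L{i}", "edge": "E1", "status": "ok",
                 "delta": d, "delta_per_base": d / 100,
                 "linkage": lk}
                for i, (d, lk) in enumerate(
                    [(3, "A"), (5, "A"), (-1, "X"), (-2, "X")])]
        summ, reg = C.bin_signal(self._frame(rows))
        assert summ["sum_delta"].sum() == pytest.approx(5.0)
        assert reg.iloc[0]["regime"] == "discordant"

    @pytest.mark.parametrize("a_med,x_med,regime", [
        (2.0, 1.0, "concordant_weaker"),
        (1.0, 2.0, "concordant_stronger"),
        (1.0, -1.0, "discordant"),
        (-1.0, -2.0, "concordant_negative"),
    ])
    def test_regime_classification(self, a_med, x_med, regime):
        rows = []
        for i in range(3):
            rows.append({"locus": f"a{i}", "edge": "E1", "status": "ok",
                         "delta": a_med, "delta_per_base": a_med,
                         "linkage": "A"})
            rows.append({"locus": f"x{i}", "edge": "E1", "status": "ok",
                         "delta": x_med, "delta_per_base": x_med,
                         "linkage": "X"})
        _, reg = C.bin_signal(self._frame(rows))
        assert reg.iloc[0]["regime"] == regime

    def test_single_bin_warns(self):
        rows = [{"locus": "L1", "edge": "E1", "status": "ok", "delta": 1.0,
                 "delta_per_base": 0.01, "linkage": "A"}]
        with pytest.warns(UserWarning):
            summ, reg = C.bin_signal(self._frame(rows))
        assert len(reg) == 0
        assert set(summ["linkage"]) == {"A"}


class TestNt12:
    def test_lengths_reduced_by_third(self, small_locus_set):
        _, _, recs, _ = small_locus_set
        corrected = C.nt12_correction(recs[:4])
        for orig, cor in zip(recs, corrected):
            assert cor.alignment.length == 2 * orig.alignment.length // 3

    def test_idempotent(self, small_locus_set):
        _, _, recs, _ = small_locus_set
        once = C.nt12_correction(recs[:3])
        with pytest.warns(UserWarning):
            twice = C.nt12_correction(once)
        assert [r.alignment.length for r in twice] == \
            [r.alignment.length for r in once]
        assert all(a.alignment == b.alignment
                   for a, b in zip(once, twice))


class TestTreeDistanceMatrix:
    def test_identical_trees_zero_matrix(self, rng):
        t = T.random_binary_tree([f"T{i}" for i in range(8)], rng)
        dm = C.tree_distance_matrix([T.clone(t) for _ in range(4)])
        assert np.allclose(dm, 0)

    def test_symmetric_zero_diagonal(self, rng):
        trees = [T.random_binary_tree([f"T{i}" for i in range(8)], rng)
                 for _ in range(5)]
        dm = C.tree_distance_matrix(trees, support_collapse=None)
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)

    def test_collapse_distance_bound(self, rng):
        """wRF after collapsing weak edges exceeds the uncollapsed wRF by
        at most the collapsed branch weight."""
        labels = [f"T{i}" for i in range(10)]
        for _ in range(30):
            t1 = T.random_binary_tree(labels, rng)
            t2 = T.random_binary_tree(labels, rng)
            collapsed_w = 0.0
            for t in (t1, t2):
                for nd in t.preorder_internal_node_iter():
                    if nd.parent_node is None:
                        continue
                    sup = float(rng.integers(0, 101))
                    nd.label = str(sup)
                    nd.edge.length = float(rng.uniform(0.01, 0.5))
                    if sup < 50:
                        collapsed_w += nd.edge.length
            before = T.rf_distance(t1, t2, weighted=True)
            after = T.rf_distance(T.collapse_low_support(t1, 50),
                                  T.collapse_low_support(t2, 50),
                                  weighted=True)
            assert after <= before + collapsed_w + 1e-9


class TestPcoa:
    def test_collinear_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = C.pcoa(d)
        assert (res.eigenvalues > 1e-9).sum() == 1
        got = np.abs(res.coordinates[:, 0] - res.coordinates[:, 0][:, None])
        assert np.allclose(got, d, atol=1e-9)

    def test_recovers_euclidean_2d(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = C.pcoa(d)
        rec = np.linalg.norm(res.coordinates[:, None, :2]
                             - res.coordinates[None, :, :2], axis=2)
        assert np.allclose(rec, d, atol=1e-9)

    def test_zero_matrix(self):
        res = C.pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0 or \
            np.allclose(res.coordinates, 0)

    def test_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = C.pcoa(d)
        skbio = pytest.importorskip("skbio")
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        ev_ref = np.sort(ref.eigvals.values)[::-1][:3]
        assert np.allclose(np.sort(res.eigenvalues)[::-1][:3], ev_ref,
                           atol=1e-8)


class TestGroves:
    def test_k1_and_determinism(self, rng):
        coords = rng.normal(size=(20, 3))
        one = C.cluster_groves(coords, 1, seed=0)
        assert set(one.labels) == {1}
        a = C.cluster_groves(coords, 3, seed=5)
        b = C.cluster_groves(coords, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)
        with pytest.raises(ValueError):
            C.cluster_groves(coords, 21, seed=0)

    def test_two_planted_groups_recovered(self, rng):
        t1 = T.random_binary_tree([f"T{i}" for i in range(10)], rng)
        t2 = T.random_binary_tree([f"T{i}" for i in range(10)], rng)
        recs = []
        truth = []
        for i in range(40):
            src = t1 if i % 2 == 0 else t2
            truth.append(i % 2)
            recs.append(LocusRecord(f"L{i}", None, T.clone(src), "A"))
        ga = C.grove_pipeline(recs, k=2, seed=3, support_collapse=None)
        assert adjusted_rand_score(truth, ga.labels) >= 0.9

    def test_composition_matches_reference_proportion(self):
        n, n_x = 2286, 145
        linkage = pd.Series(["X"] * n_x + ["A"] * (n - n_x),
                            index=[f"L{i}" for i in range(n)])
        ga = C.GroveAssignment(np.ones(n, int), np.zeros((n, 1)),
                               np.array([]), list(linkage.index))
        comp = C.grove_composition(ga, linkage).set_index("grove")
        assert comp.loc["TOTAL", "pct_X_rounded"] == 6
        assert comp.loc["TOTAL", "pct_X"] == pytest.approx(100 * 145 / 2286)
        assert comp.loc["1", "n_X"] == comp.loc["TOTAL", "n_X"]

    def test_composition_additivity(self, rng):
        labels = rng.integers(1, 4, size=30)
        linkage = pd.Series(rng.choice(["A", "X"], 30),
                            index=[f"L{i}" for i in range(30)])
        ga = C.GroveAssignment(labels, np.zeros((30, 2)), np.array([]),
                               list(linkage.index))
        comp = C.grove_composition(ga, linkage).set_index("grove")
        per_grove = comp.drop("TOTAL")
        assert per_grove["n_X"].sum() == comp.loc["TOTAL", "n_X"]
        assert per_grove["n_loci"].sum() == comp.loc["TOTAL", "n_loci"]


class TestTopologySpace:
    def test_outlier_tree_separates(self, rng):
        base = T.random_binary_tree([f"T{i}" for i in range(10)], rng)
        diff = T.random_binary_tree([f"T{i}" for i in range(10)],
                                    np.random.default_rng(123))
        named = {"a": T.clone(base), "b": T.clone(base),
                 "c": T.clone(base), "weird": diff}
        df = C.topology_space(named).set_index("name")
        assert df["PC1"].abs().idxmax() == "weird"

    def test_duplicate_tree_coincides(self, rng):
        base = T.random_binary_tree([f"T{i}" for i in range(8)], rng)
        other = T.random_binary_tree([f"T{i}" for i in range(8)],
                                     np.random.default_rng(9))
        named = {"a": T.clone(base), "b": T.clone(base), "c": other}
        df = C.topology_space(named).set_index("name")
        assert np.allclose(df.loc["a"].values, df.loc["b"].values,
                           atol=1e-9)
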