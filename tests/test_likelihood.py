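import math

import numpy as np
import pytest

from xgrove import trees as T
from xgrove.alignment import Alignment
from xgrove.substitution import (BL_MIN, GTRModel, ModelError,
                                 TreeLikelihood, discrete_gamma_rates,
                                 simulate_alignment)
from _oracles import brute_force_log_likelihood


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, gtr_model):
        assert np.allclose(gtr_model.transition_matrix(0.0), np.eye(4))

    def test_jc_closed_form(self):
        m = GTRModel.jc69()
        t = 0.16736
        p = m.transition_matrix(t)
        off = (1 - math.exp(-4 * t / 3)) / 4
        assert p[0, 1] == pytest.approx(off, abs=1e-12)
        assert p[0, 0] == pytest.approx(1 - 3 * off, abs=1e-12)

    def test_rows_sum_to_one(self, gtr_model):
        for t in (0.01, 0.5, 3.0):
            assert np.allclose(gtr_model.transition_matrix(t).sum(1), 1,
                               atol=1e-12)

    def test_chapman_kolmogorov(self, gtr_model):
        pa = gtr_model.transition_matrix(0.12)
        pb = gtr_model.transition_matrix(0.31)
        assert np.allclose(pa @ pb, gtr_model.transition_matrix(0.43),
                           atol=1e-10)

    def test_stationary_limit(self, gtr_model):
        p = gtr_model.transition_matrix(80.0)
        assert np.allclose(p, np.asarray(gtr_model.freqs)[None, :],
                           atol=1e-8)

    def test_negative_time_rejected(self, gtr_model):
        with pytest.raises(ModelError):
            gtr_model.transition_matrix(-0.1)

    def test_gamma_rates_mean_one(self):
        for a in (0.2, 0.8, 5.0):
            r = discrete_gamma_rates(a, 4)
            assert r.mean() == pytest.approx(1.0)
            assert np.all(np.diff(r) > 0)


class TestPruningLikelihood:
    def test_matches_exhaustive_oracle(self, rng, gtr_model):
        """Pruning equals the sum over all internal-state assignments."""
        for n in (4, 5):
            t = T.random_binary_tree([f"T{i}" for i in range(n)], rng)
            for nd in t.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length = float(rng.uniform(0.02, 0.6))
            aln = simulate_alignment(t, gtr_model, 30, rng=rng)
            mine = TreeLikelihood(aln, t, gtr_model).log_likelihood()
            oracle = brute_force_log_likelihood(aln, t, gtr_model)
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_reroot_invariance(self, quartet, gtr_model, rng):
        aln = simulate_alignment(quartet, gtr_model, 50, rng=rng)
        base = TreeLikelihood(aln, quartet, gtr_model).log_likelihood()
        t2 = T.clone(quartet)
        t2.reroot_at_edge(t2.find_node_with_taxon_label("C").edge,
                          length1=0.1, length2=0.2)
        assert TreeLikelihood(aln, t2, gtr_model).log_likelihood() == \
            pytest.approx(base, abs=1e-8)

    def test_leaf_order_invariance(self, quartet, gtr_model, rng):
        aln = simulate_alignment(quartet, gtr_model, 40, rng=rng)
        shuffled = aln.select_taxa(aln.taxa[::-1])
        assert TreeLikelihood(shuffled, quartet, gtr_model).log_likelihood() \
            == pytest.approx(
                TreeLikelihood(aln, quartet, gtr_model).log_likelihood(),
                abs=1e-10)

    def test_all_missing_taxon_marginalises_out(self, quartet, gtr_model,
                                                rng):
        aln = simulate_alignment(quartet, gtr_model, 40, rng=rng)
        seqs = {t: aln.sequence(t) for t in aln.taxa}
        seqs["D"] = "N" * aln.length
        masked = Alignment(list(seqs), list(seqs.values()))
        pruned_lnl = TreeLikelihood(aln.drop_taxon("D"),
                                    T.prune_taxon(quartet, "D"),
                                    gtr_model).log_likelihood()
        assert TreeLikelihood(masked, quartet, gtr_model).log_likelihood() \
            == pytest.approx(pruned_lnl, abs=1e-8)

    def test_per_site_sums_to_total(self, quartet, gtr_model, rng):
        aln = simulate_alignment(quartet, gtr_model, 60, rng=rng)
        res = TreeLikelihood(aln, quartet, gtr_model).result()
        assert res.per_site_log_likelihoods.sum() == pytest.approx(
            res.log_likelihood, abs=1e-9)


class TestBranchOptimisation:
    def test_recovers_lengths(self, gtr_model):
        t = T.read_newick("(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
                          "(E:0.1,F:0.1):0.1,(G:0.1,H:0.1):0.1);")
        aln = simulate_alignment(t, gtr_model, 10000,
                                 rng=np.random.default_rng(7))
        tl = TreeLikelihood(aln, t, gtr_model, use_tree_lengths=False,
                            init_length=0.05)
        tl.optimize_branch_lengths()
        got = tl.branch_lengths[tl._parent >= 0]
        assert np.all(np.abs(got - 0.1) < 0.03)

    def test_monotone_and_beats_start(self, quartet, gtr_model, rng):
        aln = simulate_alignment(quartet, gtr_model, 300, rng=rng)
        tl = TreeLikelihood(aln, quartet, gtr_model, use_tree_lengths=False,
                            init_length=0.4)
        start = tl.log_likelihood()
        res = tl.optimize_branch_lengths()
        assert res.log_likelihood >= start

    def test_zero_variation_collapses_lengths(self, quartet, gtr_model):
        aln = Alignment(["A", "B", "C", "D"], ["ACGT" * 5] * 4)
        tl = TreeLikelihood(aln, quartet, gtr_model)
        tl.optimize_branch_lengths()
        assert np.all(tl.branch_lengths[tl._parent >= 0] < 1e-4)

    def test_generating_topology_preferred(self, gtr_model):
        """The generating topology outscores every NNI neighbour for
        nearly all simulated loci."""
        t = T.read_newick("(((A:0.08,B:0.08):0.06,(C:0.08,D:0.08):0.06)"
                          ":0.06,(E:0.08,F:0.08):0.06,(G:0.08,H:0.08):0.06);")
        wins = 0
        n_rep = 25
        for rep in range(n_rep):
            aln = simulate_alignment(t, gtr_model, 500,
                                     rng=np.random.default_rng(100 + rep))
            ref = TreeLikelihood(aln, t, gtr_model)
            lnl_ref = ref.optimize_branch_lengths(max_rounds=5,
                                                  lnl_tol=1e-2).log_likelihood
            ok = all(
                TreeLikelihood(aln, nb, gtr_model).optimize_branch_lengths(
                    max_rounds=5, lnl_tol=1e-2).log_likelihood <= lnl_ref + 1e-6
                for nb in T.nni_neighbors(t))
            wins += ok
        assert wins >= 0.95 * n_rep


class TestSimulation:
    def test_deterministic_under_seed(self, quartet, gtr_model):
        a1 = simulate_alignment(quartet, gtr_model, 100,
                                rng=np.random.default_rng(3))
        a2 = simulate_alignment(quartet, gtr_model, 100,
                                rng=np.random.default_rng(3))
        assert a1 == a2

    def test_zero_lengths_identical_sequences(self, gtr_model):
        t = T.read_newick("((A:0,B:0):0,C:0,D:0);")
        aln = simulate_alignment(t, gtr_model, 200,
                                 rng=np.random.default_rng(1))
        ref = aln.sequence("A")
        assert all(aln.sequence(x) == ref for x in "BCD")

    def test_expected_p_distance_two_taxa(self):
        m = GTRModel.jc69()
        d = 0.3
        t = T.read_newick(f"(A:{d / 2},B:{d / 2});")
        n = 10000
        aln = simulate_alignment(t, m, n, rng=np.random.default_rng(9))
        p_exp = 0.75 * (1 - math.exp(-4 * d / 3))
        p_obs = np.mean(np.array(list(aln.sequence("A")))
                        != np.array(list(aln.sequence("B"))))
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se
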