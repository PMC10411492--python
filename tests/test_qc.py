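import numpy as np
import pandas as pd
import pytest

import xgrove as xg
from xgrove import trees as T
from xgrove.alignment import Alignment
from xgrove.qc import (LocusRecord, detect_contamination,
                       filter_distance_outliers, filter_long_branches,
                       filter_rf_outliers, filter_short_loci,
                       run_qc_cascade)
from xgrove.substitution import GTRModel, simulate_alignment


def _record(locus_id, aln, tree, linkage="A"):
    return LocusRecord(locus_id, aln, tree, linkage)


def _sim_record(tree, length=300, seed=0, locus_id="L1"):
    m = GTRModel(freqs=(0.3, 0.2, 0.3, 0.2),
                 rates=(1.5, 3.0, 0.8, 1.2, 4.0, 1.0), alpha=0.8)
    aln = simulate_alignment(tree, m, length,
                             rng=np.random.default_rng(seed))
    return _record(locus_id, aln, T.clone(tree))


class TestLongBranches:
    def test_equal_edges_no_removal(self, rng):
        t = T.random_binary_tree([f"T{i}" for i in range(8)], rng)
        rec = _sim_record(t)
        rep = filter_long_branches(rec)
        assert rep.actions == []

    def test_100_edge_arithmetic(self, rng):
        # 99 edges at 0.01 and one terminal at 1.0: mean 0.0199,
        # 50 x mean = 0.995 < 1.0 -> removed
        labels = [f"T{i:02d}" for i in range(51)]
        t = T.random_binary_tree(labels, rng)
        # root on an edge: a rooted 51-leaf binary tree has 100 edges
        t.is_rooted = True
        t.reroot_at_edge(t.find_node_with_taxon_label("T20").edge)
        edges = [nd for nd in t.preorder_node_iter() if nd.parent_node]
        assert len(edges) == 100
        for nd in edges:
            nd.edge.length = 0.01
        t.find_node_with_taxon_label("T05").edge.length = 1.0
        rec = _record("L1", Alignment(labels, ["ACGT" * 3] * len(labels)), t)
        rep = filter_long_branches(rec)
        assert [a["taxon"] for a in rep.actions] == ["T05"]
        assert "T05" not in rec.alignment

    def test_small_tree_insensitivity(self):
        # 5 edges: 4 at 0.01, terminal at 10 -> 50 x mean 100.4 > 10: kept
        t = T.read_newick("((A:0.01,B:0.01):0.01,C:0.01,D:10);")
        rec = _record("L1", Alignment(list("ABCD"), ["ACGTAC"] * 4), t)
        rep = filter_long_branches(rec)
        assert rep.actions == []

    def test_iterates_to_fixed_point(self, rng):
        labels = [f"T{i:02d}" for i in range(40)]
        t = T.random_binary_tree(labels, rng)
        for nd in t.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.01
        # one huge and one merely large outlier: the huge one inflates the
        # mean enough to shelter the second until it is removed
        t.find_node_with_taxon_label("T01").edge.length = 60.0
        t.find_node_with_taxon_label("T02").edge.length = 1.5
        rec = _record("L1", Alignment(labels, ["ACGTAC"] * 40), t)
        rep = filter_long_branches(rec)
        assert {a["taxon"] for a in rep.actions} == {"T01", "T02"}


class TestContamination:
    def _setup(self, rng, seed=0):
        st = T.random_binary_tree([f"T{i:02d}" for i in range(10)], rng)
        for nd in st.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.08
        rec = _sim_record(st, length=600, seed=seed)
        concat = pd.DataFrame(0.35, index=rec.alignment.taxa,
                              columns=rec.alignment.taxa)
        np.fill_diagonal(concat.values, 0.0)
        return st, rec, concat

    def test_clean_locus_no_actions(self, rng):
        st, rec, concat = self._setup(rng)
        rep = detect_contamination(rec, concat, st)
        assert rep.actions == []

    def test_contaminant_removed_donor_kept(self, rng):
        st, rec, concat = self._setup(rng, seed=1)
        # copy T03's sequence onto T07 and regraft accordingly
        seqs = {t: rec.alignment.sequence(t) for t in rec.alignment.taxa}
        seqs["T07"] = seqs["T03"]
        rec.alignment = Alignment(list(seqs), list(seqs.values()))
        from xgrove.simulate import _regraft_as_sister
        rec.tree = _regraft_as_sister(rec.tree, mobile="T07", target="T03")
        rep = detect_contamination(rec, concat, st)
        assert [(a["taxon"], a["rule"]) for a in rep.actions] == \
            [("T07", "contamination")]
        assert "T03" in rec.alignment and "T07" not in rec.alignment

    def test_tie_removes_both(self, rng):
        # both drop-tests give RF 0: gene tree fully concordant, so the
        # identical pair is symmetric evidence and both are removed
        st, rec, concat = self._setup(rng, seed=2)
        seqs = {t: rec.alignment.sequence(t) for t in rec.alignment.taxa}
        seqs["T07"] = seqs["T03"]
        rec.alignment = Alignment(list(seqs), list(seqs.values()))
        rep = detect_contamination(rec, concat, st)
        assert {a["taxon"] for a in rep.actions} == {"T03", "T07"}

    def test_distant_pairs_ignored(self, rng):
        st, rec, concat = self._setup(rng, seed=3)
        concat.loc[:, :] = 0.05  # below d_concat_min: nothing suspect
        seqs = {t: rec.alignment.sequence(t) for t in rec.alignment.taxa}
        seqs["T07"] = seqs["T03"]
        rec.alignment = Alignment(list(seqs), list(seqs.values()))
        rep = detect_contamination(rec, concat, st)
        assert rep.actions == []


class TestDistanceOutliers:
    def test_homogeneous_locus_no_removals(self, rng):
        t = T.random_binary_tree([f"T{i:02d}" for i in range(12)], rng)
        for nd in t.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.05
        rec = _sim_record(t, length=500)
        rep = filter_distance_outliers(rec, k=3)
        assert rep.actions == []

    def test_randomised_sequence_removed(self, rng):
        t = T.random_binary_tree([f"T{i:02d}" for i in range(12)], rng)
        for nd in t.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.03
        rec = _sim_record(t, length=500, seed=4)
        seqs = {x: rec.alignment.sequence(x) for x in rec.alignment.taxa}
        seqs["T04"] = "".join(rng.choice(list("ACGT"), 500))
        rec.alignment = Alignment(list(seqs), list(seqs.values()))
        rep = filter_distance_outliers(rec, k=3)
        assert [a["taxon"] for a in rep.actions] == ["T04"]

    def test_infinite_k_no_removals(self, rng):
        t = T.random_binary_tree([f"T{i}" for i in range(8)], rng)
        rec = _sim_record(t, length=200, seed=5)
        assert filter_distance_outliers(rec, k=np.inf).actions == []


class TestLocusDrops:
    def test_short_locus_boundary(self):
        t = T.read_newick("((A:1,B:1):1,C:1,D:1);")
        recs = [
            _record("l149", Alignment(list("ABCD"), ["A" * 149] * 4), t),
            _record("l150", Alignment(list("ABCD"), ["A" * 150] * 4), t),
        ]
        kept, rep = filter_short_loci(recs)
        assert [r.id for r in kept] == ["l150"]
        assert rep.drops[0]["locus"] == "l149"
        assert filter_short_loci([])[0] == []

    def test_rf_outliers(self, rng):
        st = T.random_binary_tree([f"T{i:02d}" for i in range(12)], rng)
        for nd in st.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.1
        concordant = [_record(f"c{i}", Alignment(
            [f"T{j:02d}" for j in range(12)], ["ACGTAC"] * 12), T.clone(st))
            for i in range(29)]
        rogue_tree = T.random_binary_tree([f"T{i:02d}" for i in range(12)],
                                          np.random.default_rng(777))
        for nd in rogue_tree.preorder_node_iter():
            if nd.parent_node:
                nd.edge.length = 0.1
        rogue = _record("rogue", Alignment(
            [f"T{j:02d}" for j in range(12)], ["ACGTAC"] * 12), rogue_tree)
        kept, rep = filter_rf_outliers(concordant + [rogue], st)
        assert [d["locus"] for d in rep.drops] == ["rogue"]
        kept2, rep2 = filter_rf_outliers(concordant + [rogue], st, k=np.inf)
        assert len(kept2) == 30

    def test_rf_outliers_few_loci_warns(self, rng):
        st = T.random_binary_tree([f"T{i}" for i in range(6)], rng)
        recs = [_record("a", Alignment([f"T{i}" for i in range(6)],
                                       ["ACGTAC"] * 6), T.clone(st))]
        with pytest.warns(UserWarning):
            kept, _ = filter_rf_outliers(recs, st)
        assert len(kept) == 1


class TestCascade:
    def test_idempotent_on_demo_preset(self):
        cfg = xg.preset("contamination_demo", n_autosomal_loci=15,
                        n_contaminants=3, n_long_branches=2, seed=21)
        rng = np.random.default_rng(cfg.seed)
        st = xg.simulate_species_tree(cfg, rng=rng)
        recs, truth = xg.simulate_locus_set(cfg, species_tree=st, rng=rng)
        kept, rep1 = run_qc_cascade(recs, st)
        kept2, rep2 = run_qc_cascade(kept, st)
        assert rep2.actions == []
        assert [d for d in rep2.drops] == []
        assert [r.id for r in kept2] == [r.id for r in kept]
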