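"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the likelihood oracle
enumerates internal-state assignments directly from the Newick structure,
and the split oracle relies on dendropy's own bipartition machinery.
"""

import itertools
import math

import dendropy
import numpy as np

from xgrove import trees as T


def brute_force_log_likelihood(aln, tree, model):
    """Exhaustive sum over all internal-node state assignments.

    Only feasible for tiny trees (4^k assignments for k internal nodes).
    """
    t = T._deroot(T.clone(tree))
    nodes = list(t.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    codes = aln.codes()
    row = {lab: i for i, lab in enumerate(aln.taxa)}
    pi = np.asarray(model.freqs)
    gamma = model.gamma_rates
    total = 0.0
    for s in range(aln.length):
        site_like = 0.0
        for r in gamma:
            P = {id(nd): model.transition_matrix(nd.edge.length or 0.0, r)
                 for nd in nodes if nd.parent_node is not None}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                state = {id(nd): a for nd, a in zip(internals, assign)}
                p = pi[state[id(t.seed_node)]]
                for nd in nodes:
                    if nd.parent_node is None:
                        continue
                    ps = state[id(nd.parent_node)]
                    if nd.is_leaf():
                        c = codes[row[nd.taxon.label], s]
                        p *= (P[id(nd)][ps].sum() if c >= 4
                              else P[id(nd)][ps, c])
                    else:
                        p *= P[id(nd)][ps, state[id(nd)]]
                acc += p
            site_like += acc / len(gamma)
        total += math.log(site_like)
    return total


def dendropy_rf(t1, t2):
    """Unweighted RF via dendropy's bipartition encoding (shared taxon
    namespace built from scratch)."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=T.write_newick(t1), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    b = dendropy.Tree.get(data=T.write_newick(t2), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


def all_unrooted_topologies(labels):
    """All unrooted binary topologies (as Newick strings) by recursive
    edge insertion: (2n-5)!! trees."""
    base = f"({labels[0]},{labels[1]},{labels[2]});"
    trees = [T.read_newick(base)]
    for lab in labels[3:]:
        nxt = []
        for tr in trees:
            edges = [nd for nd in tr.preorder_node_iter()
                     if nd.parent_node is not None]
            for k in range(len(edges)):
                t2 = T.clone(tr)
                nd = [m for m in t2.preorder_node_iter()
                      if m.parent_node is not None][k]
                parent = nd.parent_node
                parent.remove_child(nd)
                mid = parent.new_child(edge_length=1.0)
                mid.add_child(nd)
                nd.edge.length = 1.0
                tx = t2.taxon_namespace.new_taxon(label=lab)
                mid.new_child(taxon=tx, edge_length=1.0)
                nxt.append(T.read_newick(T.write_newick(t2)))
        trees = nxt
    return trees


def column_stats_bruteforce(aln):
    """Independent recomputation of missing proportion and the
    parsimony-informative fraction, character by character."""
    miss = 0
    informative = 0
    for col in range(aln.length):
        chars = [aln.sequence(t)[col] for t in aln.taxa]
        miss += sum(c in "-N" for c in chars)
        counts = {}
        for c in chars:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return {"missing_prop": miss / (aln.length * aln.n_taxa),
            "pis_prop": informative / aln.length}
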