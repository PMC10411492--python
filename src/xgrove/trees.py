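"""Tree topology operations on dendropy trees.

Trees are plain :class:`dendropy.Tree` objects; branch lengths live on
``edge.length`` and node support (0-100, RAxML-style internal node labels)
on ``node.label``. All functions here treat trees as unrooted: a rooted
bifurcation at the seed node is handled transparently (its two seed edges
describe one unrooted edge).

Splits are represented as frozensets of leaf labels, canonicalised to the
side *not* containing the lexicographically smallest leaf, so that the two
sides of a bipartition map to the same key.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Sequence

import dendropy


class TreeError(ValueError):
    pass


# -- I/O -----------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string.

    Internal node labels are kept verbatim (interpreted downstream as
    support values when numeric); underscores in labels are preserved.
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True,
                       real_value_format_specifier=".12g")
    if path is not None:
        Path(path).write_text(s)
    return s


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    return read_newick(write_newick(tree))


# -- basic queries -------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def node_support(node: dendropy.Node) -> float | None:
    """Support value stored as an internal node label, if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges() if e.head_node.parent_node)


def mean_branch_length(tree: dendropy.Tree) -> float:
    lens = [e.length or 0.0 for e in tree.edges() if e.head_node.parent_node]
    return sum(lens) / len(lens) if lens else 0.0


def mean_support(tree: dendropy.Tree) -> float | None:
    vals = [node_support(nd) for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None]
    vals = [v for v in vals if v is not None]
    return sum(vals) / len(vals) if vals else None


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """All-pairs path lengths between leaves, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for t1, t2 in itertools.combinations(taxa, 2):
        out[tuple(sorted((t1.label, t2.label)))] = pdm.patristic_distance(t1, t2)
    return out


# -- splits and RF distances --------------------------------------------

def splits(tree: dendropy.Tree, weighted: bool = False):
    """Non-trivial bipartitions induced by internal edges.

    Returns a set of frozensets, or with ``weighted=True`` a dict mapping
    split -> summed branch length (a rooted seed bifurcation contributes
    the sum of its two seed edges to the single unrooted split).
    """
    leaves = leaf_labels(tree)
    if len(leaves) < 4:
        return {} if weighted else set()
    anchor = min(leaves)
    acc: dict[frozenset, float] = {}
    # postorder accumulation of leaf sets below each node
    below: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in
                                                nd.child_nodes()))
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = below[id(nd)]
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = frozenset(other) if anchor in side else side
        acc[key] = acc.get(key, 0.0) + (nd.edge.length or 0.0)
    return acc if weighted else set(acc)


def restrict_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Copy of ``tree`` pruned to ``taxa``; unifurcations suppressed with
    branch lengths summed."""
    taxa = set(taxa)
    t = clone(tree)
    keep = [tx for tx in t.taxon_namespace if tx.label in taxa]
    if len(keep) < len(taxa):
        missing = taxa - {tx.label for tx in keep}
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    t.retain_taxa(keep)
    return t


def prune_taxon(tree: dendropy.Tree, taxon: str) -> dendropy.Tree:
    labels = leaf_labels(tree)
    if taxon not in labels:
        raise TreeError(f"unknown taxon: {taxon}")
    return restrict_to_taxa(tree, labels - {taxon})


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree,
                weighted: bool = False) -> float:
    """Robinson-Foulds distance, automatically restricted to shared leaves.

    Unweighted: number of non-trivial splits present in exactly one tree.
    Weighted: sum over the union of splits of ``|w1 - w2|`` with weight 0
    for a split absent from a tree (internal edges only).
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    shared = l1 & l2
    if len(shared) < 4:
        raise TreeError(f"only {len(shared)} shared taxa (need >= 4)")
    if shared != l1:
        t1 = restrict_to_taxa(t1, shared)
    if shared != l2:
        t2 = restrict_to_taxa(t2, shared)
    if not weighted:
        s1, s2 = splits(t1), splits(t2)
        return float(len(s1 ^ s2))
    w1, w2 = splits(t1, weighted=True), splits(t2, weighted=True)
    return float(sum(abs(w1.get(k, 0.0) - w2.get(k, 0.0))
                     for k in set(w1) | set(w2)))


# -- support collapsing --------------------------------------------------

def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract internal edges whose child-node support is strictly below
    ``threshold`` (percent). Edges without a numeric support are retained."""
    if not 0 <= threshold <= 100:
        raise TreeError(f"threshold must be within [0, 100]: {threshold}")
    t = clone(tree)
    doomed = []
    for nd in t.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        sup = node_support(nd)
        if sup is not None and sup < threshold:
            doomed.append(nd)
    for nd in doomed:
        nd.edge.collapse()
    return t


# -- NNI -----------------------------------------------------------------

def _deroot(tree: dendropy.Tree) -> dendropy.Tree:
    t = clone(tree)
    t.is_rooted = False
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()
    return t


def _check_unrooted_binary(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_internal_node_iter():
        k = len(nd.child_nodes())
        expect = 3 if nd.parent_node is None else 2
        if k != expect:
            raise TreeError("nni_neighbors requires an unrooted binary tree")


def _internal_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Internal edges as their child (head) nodes, preorder."""
    return [nd for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None]


def _swap(parent_child: dendropy.Node, a: dendropy.Node, b: dendropy.Node
          ) -> None:
    """Exchange subtree ``a`` (child of the edge's head node) with subtree
    ``b`` (another child of the edge's tail node)."""
    c = parent_child
    p = c.parent_node
    c.remove_child(a)
    p.remove_child(b)
    p.add_child(a)
    c.add_child(b)


def nni_neighbors(tree: dendropy.Tree, edge_index: int | None = None
                  ) -> list[dendropy.Tree]:
    """All nearest-neighbour-interchange topologies of an unrooted binary
    tree: two per internal edge, 2(n-3) in total; ``edge_index`` (preorder
    position among internal edges) limits to one edge."""
    base = _deroot(tree)
    _check_unrooted_binary(base)
    n_int = len(_internal_edges(base))
    if edge_index is None:
        idxs = range(n_int)
    else:
        if not 0 <= edge_index < n_int:
            raise TreeError(f"internal edge index out of range: {edge_index}")
        idxs = [edge_index]
    out = []
    for i in idxs:
        for which in (0, 1):
            t = clone(base)
            c = _internal_edges(t)[i]
            p = c.parent_node
            sib = next(ch for ch in p.child_nodes() if ch is not c)
            x = c.child_nodes()[which]
            _swap(c, x, sib)
            out.append(t)
    return out


def nni_neighbors_for_split(tree: dendropy.Tree, split: frozenset
                            ) -> list[dendropy.Tree]:
    """The two NNI rearrangements around the internal edge inducing
    ``split`` (canonicalised as in :func:`splits`)."""
    base = _deroot(tree)
    _check_unrooted_binary(base)
    leaves = leaf_labels(base)
    anchor = min(leaves)
    for i, nd in enumerate(_internal_edges(base)):
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = frozenset(leaves - side) if anchor in side else side
        if key == split:
            return nni_neighbors(tree, edge_index=i)
    raise TreeError("no internal edge induces the requested split")


# -- random trees (test/simulation support) -------------------------------

def random_binary_tree(labels: Sequence[str], rng) -> dendropy.Tree:
    """Uniform-ish random unrooted binary topology by sequential leaf
    addition onto a random edge; unit branch lengths."""
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("need >= 3 labels")
    newick = f"({labels[0]}:1,{labels[1]}:1,{labels[2]}:1);"
    t = read_newick(newick)
    for lab in labels[3:]:
        edges = [e for e in t.edges() if e.head_node.parent_node is not None]
        e = edges[int(rng.integers(len(edges)))]
        head = e.head_node
        tail = e.tail_node
        tail.remove_child(head)
        mid = tail.new_child(edge_length=0.5)
        mid.add_child(head)
        head.edge.length = 0.5
        tx = t.taxon_namespace.new_taxon(label=lab)
        mid.new_child(taxon=tx, edge_length=1.0)
    return read_newick(write_newick(t))
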