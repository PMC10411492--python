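"""Gene-conflict interrogation.

Quantifies, per locus and per focal edge of a reference species tree, the
log-likelihood advantage of the reference resolution over its best
nearest-neighbour-interchange alternative (rescaled per base so long loci
do not dominate), sums and bins that signal by chromosomal linkage,
re-runs the analysis after third-codon-position exclusion, and clusters
gene trees into "groves" by weighted Robinson-Foulds distance through
principal-coordinates analysis.

Sign convention: ``delta = lnL_ref - lnL_best_alt`` is positive when the
locus favours the reference resolution of the focal edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .alignment import Alignment
from . import trees as T
from .qc import LocusRecord
from .substitution import GTRModel, TreeLikelihood, fit_model


# ======================================================================
# Per-locus, per-edge likelihood signal
# ======================================================================

@dataclass
class FocalEdge:
    """A focal internal edge of the species tree, identified by the
    bipartition it induces (canonicalised as in :func:`xgrove.trees.splits`)."""

    name: str
    split: frozenset


def deep_focal_edges(species_tree, n: int = 1) -> list[FocalEdge]:
    """The ``n`` internal edges whose bipartitions are most balanced
    (deepest splits), ordered by balance; a convenient default focal set."""
    leaves = T.leaf_labels(species_tree)
    half = len(leaves) / 2
    scored = sorted(T.splits(species_tree),
                    key=lambda s: (abs(min(len(s), len(leaves) - len(s))
                                       - half), sorted(s)[0]))
    return [FocalEdge(f"E{i + 1}", s) for i, s in enumerate(scored[:n])]


def all_focal_edges(species_tree) -> list[FocalEdge]:
    return [FocalEdge(f"E{i + 1}", s)
            for i, s in enumerate(sorted(T.splits(species_tree),
                                         key=lambda s: sorted(s)))]


def delta_lnl(record: LocusRecord, species_tree,
              focal_edges: list[FocalEdge], model: GTRModel | None = None,
              max_rounds: int = 4, lnl_tol: float = 1e-2) -> list[dict]:
    """Signal rows for one locus: for each focal edge, the reference
    topology (species tree restricted to the locus taxa) and both NNI
    alternatives are scored with branch lengths re-optimised per topology
    under a fixed per-locus model; ``delta = lnL_ref - max(lnL_alts)``.

    Edges whose bipartition does not survive restriction to the locus
    taxa are skipped with a reason.
    """
    taxa = set(record.taxa)
    if len(taxa) < 4:
        return []
    ref = T.restrict_to_taxa(species_tree, taxa & T.leaf_labels(species_tree))
    ref_splits = T.splits(ref)
    if model is None:
        model = fit_model(record.alignment, record.tree)
    aln = record.alignment
    length = aln.length
    tl_ref = TreeLikelihood(aln, ref, model)
    lnl_ref = tl_ref.optimize_branch_lengths(
        max_rounds=max_rounds, lnl_tol=lnl_tol).log_likelihood
    leaves = T.leaf_labels(ref)
    anchor = min(leaves)
    rows = []
    for edge in focal_edges:
        # restrict the bipartition to the locus taxon set
        side = edge.split & leaves
        other = leaves - side
        key = frozenset(other) if anchor in side else frozenset(side)
        if len(side) < 2 or len(other) < 2 or key not in ref_splits:
            rows.append({"locus": record.id, "edge": edge.name,
                         "status": "edge_lost", "linkage": record.linkage})
            continue
        try:
            alts = T.nni_neighbors_for_split(ref, key)
            lnl_alts = []
            for alt in alts:
                tl = TreeLikelihood(aln, alt, model)
                lnl_alts.append(tl.optimize_branch_lengths(
                    max_rounds=max_rounds, lnl_tol=lnl_tol).log_likelihood)
        except Exception as exc:
            warnings.warn(f"{record.id}/{edge.name}: {exc}")
            rows.append({"locus": record.id, "edge": edge.name,
                         "status": "failed", "linkage": record.linkage})
            continue
        delta = lnl_ref - max(lnl_alts)
        rows.append({"locus": record.id, "edge": edge.name, "status": "ok",
                     "lnL_ref": lnl_ref, "lnL_best_alt": max(lnl_alts),
                     "delta": delta, "delta_per_base": delta / length,
                     "length_bp": length, "linkage": record.linkage})
    return rows


def signal_table(records, species_tree, focal_edges, models=None,
                 **kw) -> pd.DataFrame:
    """Concatenated signal rows for many loci (``models`` optionally maps
    locus id -> fitted model to reuse across analyses)."""
    rows = []
    for rec in records:
        model = (models or {}).get(rec.id)
        rows.append(pd.DataFrame(delta_lnl(rec, species_tree, focal_edges,
                                           model=model, **kw)))
    df = pd.concat([r for r in rows if len(r)], ignore_index=True)
    return df


# ======================================================================
# Linkage-binned summaries
# ======================================================================

REGIMES = ("concordant_weaker", "concordant_stronger", "discordant",
           "concordant_negative")


def bin_signal(signal: pd.DataFrame, by: str = "linkage"
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (edge, bin) signal summaries and the per-edge regime call.

    Summaries: summed delta (the aggregated evidence of the bin), median
    and IQR of the per-base signal, locus count. The regime compares the
    X and A per-base medians at each edge: both positive and X < A =
    ``concordant_weaker``; both positive and X >= A =
    ``concordant_stronger``; opposite signs = ``discordant``; both
    non-positive = ``concordant_negative``.
    """
    ok = signal[signal["status"] == "ok"].copy()
    groups = []
    for (edge, label), sub in ok.groupby(["edge", by]):
        d = sub["delta_per_base"]
        groups.append({"edge": edge, by: label, "n_loci": len(sub),
                       "sum_delta": float(sub["delta"].sum()),
                       "median_delta_per_base": float(d.median()),
                       "iqr_delta_per_base": float(d.quantile(0.75)
                                                   - d.quantile(0.25))})
    summaries = pd.DataFrame(groups)
    regimes = []
    for edge, sub in summaries.groupby("edge"):
        sub = sub.set_index(by)
        if not {"A", "X"} <= set(sub.index):
            warnings.warn(f"edge {edge}: a linkage bin is empty")
            continue
        a = sub.loc["A", "median_delta_per_base"]
        x = sub.loc["X", "median_delta_per_base"]
        if a > 0 and x > 0:
            regime = ("concordant_weaker" if x < a else "concordant_stronger")
        elif a <= 0 and x <= 0:
            regime = "concordant_negative"
        else:
            regime = "discordant"
        regimes.append({"edge": edge, "median_A": a, "median_X": x,
                        "regime": regime})
    return summaries, pd.DataFrame(regimes)


def nt12_correction(records: list[LocusRecord]) -> list[LocusRecord]:
    """Copy of the records with third codon positions excluded (the
    saturation correction). Loci that are not codon-framed are passed
    through unchanged with a warning (so applying the correction twice is
    the same as applying it once); downstream operations run unchanged on
    the corrected records."""
    out = []
    for rec in records:
        if not rec.alignment.codon_frame or rec.alignment.length % 3 != 0:
            warnings.warn(f"{rec.id}: not codon-framed; passed through "
                          "uncorrected")
            out.append(rec)
            continue
        out.append(LocusRecord(rec.id, rec.alignment.codon_subset({1, 2}),
                               rec.tree, rec.linkage,
                               removed=list(rec.removed)))
    return out


# ======================================================================
# Tree space: wRF matrix, PCoA, groves
# ======================================================================

def tree_distance_matrix(gene_trees: list, support_collapse: float | None = 50,
                         weighted: bool = True) -> np.ndarray:
    """Pairwise (weighted) RF distances between gene trees, after
    collapsing weakly supported nodes; pairs with < 4 shared taxa get the
    matrix maximum as sentinel."""
    if len(gene_trees) < 3:
        raise ValueError("need >= 3 trees")
    ts = [T.collapse_low_support(t, support_collapse)
          if support_collapse is not None else t for t in gene_trees]
    n = len(ts)
    out = np.zeros((n, n))
    bad = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = T.rf_distance(ts[i], ts[j],
                                                      weighted=weighted)
            except T.TreeError:
                bad.append((i, j))
    if bad:
        mx = out.max()
        for i, j in bad:
            out[i, j] = out[j, i] = mx
        warnings.warn(f"{len(bad)} tree pairs share < 4 taxa; "
                      "set to matrix max")
    return out


@dataclass
class PCoAResult:
    coordinates: np.ndarray   # (n, n_positive_axes)
    eigenvalues: np.ndarray   # all eigenvalues, descending (may be < 0)

    def axes_for_mass(self, mass: float = 0.8) -> int:
        pos = self.eigenvalues[self.eigenvalues > 0]
        if pos.size == 0:
            return 0
        cum = np.cumsum(pos) / pos.sum()
        return int(np.searchsorted(cum, mass) + 1)


def pcoa(dist: np.ndarray, m: int | None = None) -> PCoAResult:
    """Classical metric scaling: double-centre -0.5 J D^2 J, eigendecompose,
    scale positive-eigenvalue axes by sqrt(eigenvalue). All eigenvalues are
    reported (negative ones diagnose non-Euclidean distances); coordinates
    use only positive axes, truncated to ``m`` if given.
    """
    d = np.asarray(dist, float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    lam, v = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(lam)[::-1]
    lam, v = lam[order], v[:, order]
    pos = lam > max(1e-12, 1e-10 * abs(lam[0]) if lam.size else 0)
    coords = v[:, pos] * np.sqrt(lam[pos])[None, :]
    if m is not None:
        coords = coords[:, :m]
    return PCoAResult(coords, lam)


@dataclass
class GroveAssignment:
    labels: np.ndarray            # cluster id per locus, 1..k
    coordinates: np.ndarray       # PCoA coordinates used
    eigenvalues: np.ndarray
    locus_ids: list[str]

    def composition(self, linkage: pd.Series) -> pd.DataFrame:
        return grove_composition(self, linkage)


def cluster_groves(coords: np.ndarray, k: int, seed: int,
                   eigenvalues: np.ndarray | None = None,
                   locus_ids: list[str] | None = None,
                   n_restarts: int = 50) -> GroveAssignment:
    """Centroid (k-means) clustering of loci in PCoA space; deterministic
    under a fixed seed. Cluster ids are relabelled 1..k by decreasing
    size (ties by first occurrence)."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of loci ({n})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(coords)
    sizes = pd.Series(raw).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = np.array([remap[r] for r in raw])
    return GroveAssignment(labels, coords,
                           eigenvalues if eigenvalues is not None
                           else np.array([]),
                           locus_ids or [f"L{i}" for i in range(n)])


def grove_composition(assignment: GroveAssignment, linkage: pd.Series
                      ) -> pd.DataFrame:
    """Per-grove locus counts and X-linked fractions, plus a TOTAL row
    (pct_X both raw and rounded to integer percent)."""
    lk = linkage.reindex(assignment.locus_ids)
    rows = []
    for g in sorted(set(assignment.labels)):
        sel = assignment.labels == g
        n = int(sel.sum())
        n_x = int((lk.values[sel] == "X").sum())
        rows.append({"grove": str(g), "n_loci": n, "n_X": n_x,
                     "pct_X": 100.0 * n_x / n if n else 0.0})
    n_tot = len(assignment.labels)
    n_x_tot = int((lk.values == "X").sum())
    rows.append({"grove": "TOTAL", "n_loci": n_tot, "n_X": n_x_tot,
                 "pct_X": 100.0 * n_x_tot / n_tot if n_tot else 0.0})
    df = pd.DataFrame(rows)
    df["pct_X_rounded"] = df["pct_X"].round().astype(int)
    return df


def grove_pipeline(records: list[LocusRecord], k: int, seed: int,
                   support_collapse: float | None = 50,
                   mass: float = 0.8) -> GroveAssignment:
    """wRF matrix -> PCoA -> k-means on the axes explaining ``mass`` of
    the positive eigenvalue weight."""
    dm = tree_distance_matrix([r.tree for r in records],
                              support_collapse=support_collapse)
    res = pcoa(dm)
    m = max(res.axes_for_mass(mass), 2)
    return cluster_groves(res.coordinates[:, :m], k, seed,
                          eigenvalues=res.eigenvalues,
                          locus_ids=[r.id for r in records])


def topology_space(named_trees: dict[str, object]) -> pd.DataFrame:
    """PCoA of unweighted RF distances between named analysis trees;
    returns a frame with the tree names and their coordinates."""
    names = list(named_trees)
    if len(names) < 3:
        raise ValueError("need >= 3 trees")
    dm = tree_distance_matrix([named_trees[n] for n in names],
                              support_collapse=None, weighted=False)
    res = pcoa(dm)
    cols = {f"PC{i + 1}": res.coordinates[:, i]
            for i in range(res.coordinates.shape[1])}
    df = pd.DataFrame({"name": names, **cols})
    df.attrs["eigenvalues"] = res.eigenvalues
    return df
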