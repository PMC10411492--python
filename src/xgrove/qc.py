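"""Locus hygiene cascade.

Per-locus sequence removals (long-branch paralogs, cross-contaminants,
distance outliers) and dataset-level locus drops (too-short loci, trees
with extreme distance to the species tree). Every action is recorded in a
:class:`QcReport` with the rule that fired and its numeric evidence, and
the cascade is idempotent: re-running it on its own output changes
nothing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, concatenate
from . import trees as T
from .substitution import (GTRModel, empirical_exchangeabilities,
                           empirical_frequencies, jc_distance_from_p,
                           p_distance_matrix, pairwise_distance)


@dataclass
class LocusRecord:
    """One locus: alignment + gene tree + linkage label + QC trail."""

    id: str
    alignment: Alignment
    tree: "dendropy.Tree"
    linkage: str = "unknown"  # 'A', 'X' or 'unknown'
    removed: list = field(default_factory=list)  # (taxon, rule, evidence)
    properties: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return [t for t in self.alignment.taxa if t in T.leaf_labels(self.tree)]

    def drop_taxon(self, taxon: str, rule: str, evidence: float) -> None:
        self.alignment = self.alignment.drop_taxon(taxon)
        self.tree = T.prune_taxon(self.tree, taxon)
        self.removed.append((taxon, rule, evidence))


@dataclass
class QcReport:
    """Trace of all QC decisions: per-taxon actions and per-locus drops."""

    actions: list = field(default_factory=list)  # dicts
    drops: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def add_action(self, locus: str, taxon: str, rule: str, evidence: float):
        self.actions.append({"locus": locus, "taxon": taxon, "rule": rule,
                             "evidence": float(evidence)})

    def add_drop(self, locus: str, rule: str, evidence: float):
        self.drops.append({"locus": locus, "rule": rule,
                           "evidence": float(evidence)})

    def actions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.actions,
                            columns=["locus", "taxon", "rule", "evidence"])

    def drops_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.drops, columns=["locus", "rule", "evidence"])


DEGENERATE = "degenerate"  # locus left with < 4 taxa after removals


# -- rule 1: long terminal branches --------------------------------------

def filter_long_branches(record: LocusRecord, factor: float = 50.0,
                         report: QcReport | None = None) -> QcReport:
    """Remove terminal taxa whose terminal branch exceeds ``factor`` times
    the mean edge length (mean over *all* edges, the candidate included),
    iterating until no edge qualifies."""
    report = report if report is not None else QcReport()
    while True:
        edges = [(nd, nd.edge.length or 0.0)
                 for nd in record.tree.preorder_node_iter()
                 if nd.parent_node is not None]
        if not edges:
            break
        mean = sum(l for _, l in edges) / len(edges)
        hits = [(nd.taxon.label, l) for nd, l in edges
                if nd.is_leaf() and l > factor * mean]
        if not hits or mean == 0:
            break
        for taxon, l in sorted(hits):
            record.drop_taxon(taxon, "long_branch", l / mean)
            report.add_action(record.id, taxon, "long_branch", l / mean)
        if len(T.leaf_labels(record.tree)) < 4:
            record.properties[DEGENERATE] = True
            break
    return report


# -- rule 2: cross-contamination -----------------------------------------

def detect_contamination(record: LocusRecord, concat_distances: pd.DataFrame,
                         species_tree, d_locus_max: float = 0.01,
                         d_concat_min: float = 0.2,
                         report: QcReport | None = None) -> QcReport:
    """Drop-test screen for cross-contaminant sequences.

    A pair is suspect when its within-locus GTR distance is below
    ``d_locus_max`` while its concatenation-level distance exceeds
    ``d_concat_min`` (i.e. the two samples are close here but distant
    genome-wide). For each suspect pair the gene tree is compared to the
    species tree after dropping each member in turn: the drop that yields
    the strictly smaller RF distance marks that member as the contaminant
    (removed, the donor kept); equal RF removes both.
    """
    report = report if report is not None else QcReport()
    taxa = sorted(record.taxa)
    if len(taxa) < 4:
        return report
    aln = record.alignment.select_taxa(taxa)
    model = GTRModel(freqs=tuple(empirical_frequencies(aln)),
                     rates=tuple(empirical_exchangeabilities(aln)))
    # cheap p-distance prescreen: a GTR distance < d_locus_max implies a
    # raw mismatch fraction of about the same size
    pmat = p_distance_matrix(aln)
    suspects = []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        a, b = taxa[i], taxa[j]
        try:
            d_conc = float(concat_distances.loc[a, b])
        except KeyError:
            warnings.warn(f"{record.id}: pair {a}/{b} missing from "
                          "concatenation distances; skipped")
            continue
        if d_conc <= d_concat_min or not pmat[i, j] < 3 * d_locus_max:
            continue
        d_loc = pairwise_distance(aln, a, b, "GTR", model=model)
        if d_loc < d_locus_max:
            suspects.append((a, b, d_loc, d_conc))
    gone: set[str] = set()
    for a, b, d_loc, d_conc in suspects:
        if a in gone or b in gone:
            continue
        if len(T.leaf_labels(record.tree)) - 1 < 4:
            record.properties[DEGENERATE] = True
            break
        rf_a = T.rf_distance(T.prune_taxon(record.tree, a), species_tree)
        rf_b = T.rf_distance(T.prune_taxon(record.tree, b), species_tree)
        if rf_a < rf_b:
            victims = [a]        # dropping a restores concordance
        elif rf_b < rf_a:
            victims = [b]
        else:
            victims = [a, b]     # tie: remove both
        for v in victims:
            record.drop_taxon(v, "contamination", d_loc)
            report.add_action(record.id, v, "contamination", d_loc)
            gone.add(v)
    return report


# -- rule 3: sequence-distance outliers ----------------------------------

def filter_distance_outliers(record: LocusRecord, k: float = 3.0,
                             report: QcReport | None = None) -> QcReport:
    """Remove sequences whose mean JC distance to all others exceeds
    mean + k*SD of that statistic across the locus, iterating until no
    sequence qualifies (so the filter is a projection: re-running it on
    its own output changes nothing)."""
    report = report if report is not None else QcReport()
    if not np.isfinite(k):
        return report
    while True:
        taxa = sorted(record.taxa)
        n = len(taxa)
        if n < 5:
            break
        aln = record.alignment.select_taxa(taxa)
        pmat = p_distance_matrix(aln)
        dmat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d = (np.nan if np.isnan(pmat[i, j])
                 else jc_distance_from_p(pmat[i, j]))
            if not np.isfinite(d):  # saturated or no overlap -> JC ceiling
                d = 5.0
            dmat[i, j] = dmat[j, i] = d
        means = dmat.sum(axis=1) / (n - 1)
        mu, sd = means.mean(), means.std(ddof=1)
        cut = mu + k * sd
        hits = [i for i in np.argsort(-means) if sd > 0 and means[i] > cut]
        if not hits:
            break
        for i in hits:
            record.drop_taxon(taxa[i], "distance_outlier", means[i])
            report.add_action(record.id, taxa[i], "distance_outlier",
                              means[i])
    if len(T.leaf_labels(record.tree)) < 4:
        record.properties[DEGENERATE] = True
    return report


# -- dataset-level drops -------------------------------------------------

def filter_short_loci(records: list[LocusRecord], min_bp: int = 150,
                      report: QcReport | None = None
                      ) -> tuple[list[LocusRecord], QcReport]:
    """Drop loci strictly shorter than ``min_bp`` (150 bp = 50 codons);
    a locus of exactly ``min_bp`` is retained."""
    report = report if report is not None else QcReport()
    kept = []
    for rec in records:
        if rec.alignment.length < min_bp:
            report.add_drop(rec.id, "too_short", rec.alignment.length)
        else:
            kept.append(rec)
    return kept, report


def normalized_wrf(gene_tree, species_tree) -> float:
    """Weighted RF on shared taxa, normalised by the total internal branch
    length of both restricted trees (1 = maximal disagreement)."""
    shared = T.leaf_labels(gene_tree) & T.leaf_labels(species_tree)
    g = T.restrict_to_taxa(gene_tree, shared)
    s = T.restrict_to_taxa(species_tree, shared)
    denom = (sum(T.splits(g, weighted=True).values())
             + sum(T.splits(s, weighted=True).values()))
    if denom == 0:
        return 0.0
    return T.rf_distance(g, s, weighted=True) / denom


def filter_rf_outliers(records: list[LocusRecord], species_tree,
                       rule: str = "tukey", k: float = 1.5,
                       report: QcReport | None = None
                       ) -> tuple[list[LocusRecord], QcReport]:
    """Drop loci whose normalised weighted-RF distance to the species tree
    lies above the Tukey fence Q3 + k*IQR."""
    report = report if report is not None else QcReport()
    if rule != "tukey":
        raise ValueError(f"unknown rule: {rule}")
    if len(records) < 8:
        warnings.warn("fewer than 8 loci: RF-outlier filter skipped")
        return list(records), report
    dists = np.array([normalized_wrf(r.tree, species_tree) for r in records])
    q1, q3 = np.percentile(dists, [25, 75])
    cut = q3 + k * (q3 - q1) if np.isfinite(k) else np.inf
    report.thresholds["rf_outlier_cut"] = float(cut)
    kept = []
    for rec, d in zip(records, dists):
        if d > cut:
            report.add_drop(rec.id, "rf_outlier", d)
        else:
            kept.append(rec)
    return kept, report


# -- concatenation-level distances and the full cascade -------------------

def concat_gtr_distances(records: list[LocusRecord]) -> pd.DataFrame:
    """Pairwise GTR distances on the concatenated supermatrix (symmetric
    DataFrame indexed by taxon)."""
    sup, _ = concatenate([(r.id, r.alignment) for r in records])
    model = GTRModel(freqs=tuple(empirical_frequencies(sup)),
                     rates=tuple(empirical_exchangeabilities(sup)))
    taxa = sup.taxa
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(taxa, 2):
        try:
            d = pairwise_distance(sup, a, b, "GTR", model=model)
        except Exception:
            d = np.nan
        out.loc[a, b] = out.loc[b, a] = d
    return out


def run_qc_cascade(records: list[LocusRecord], species_tree,
                   concat_distances: pd.DataFrame | None = None,
                   long_branch_factor: float = 50.0,
                   distance_k: float = 3.0, min_bp: int = 150,
                   rf_k: float = 1.5,
                   d_locus_max: float = 0.01, d_concat_min: float = 0.2,
                   ) -> tuple[list[LocusRecord], QcReport]:
    """Full hygiene cascade: long branches -> contamination -> distance
    outliers -> short-locus drop -> RF-outlier drop."""
    report = QcReport()
    if concat_distances is None:
        concat_distances = concat_gtr_distances(records)
    # distance outliers run last per locus so their fixed point is taken
    # on the final taxon set, keeping the whole cascade idempotent
    for rec in records:
        filter_long_branches(rec, factor=long_branch_factor, report=report)
        detect_contamination(rec, concat_distances, species_tree,
                             d_locus_max=d_locus_max,
                             d_concat_min=d_concat_min, report=report)
        filter_distance_outliers(rec, k=distance_k, report=report)
    dropped_degenerate = [r for r in records
                          if r.properties.get(DEGENERATE)]
    for rec in dropped_degenerate:
        report.add_drop(rec.id, DEGENERATE, len(T.leaf_labels(rec.tree)))
    records = [r for r in records if not r.properties.get(DEGENERATE)]
    records, report = filter_short_loci(records, min_bp=min_bp, report=report)
    records, report = filter_rf_outliers(records, species_tree, k=rf_k,
                                         report=report)
    return records, report
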