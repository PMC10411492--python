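"""Synthetic data generator.

Emulates the statistical structure of a chromosome-aware phylogenomic
study system: an ultrametric species tree; hundreds of codon-structured
loci of which a small fraction are X-linked with an elevated substitution
rate and strongly saturated third codon positions; gene trees drawn from
a mixture of planted "grove" topologies with NNI noise; injected
cross-contaminants and long-branch paralogs; per-sample read-depth tables
in which male X loci sit at half depth; and missing data enriched in male
X loci. Every planted fact is recorded in truth tables so downstream
filters and tests can be scored against ground truth.

Default calibration (see the methods note): species-tree height is one
time unit; an autosomal locus has a lognormal base rate with median 0.2
substitutions/site per unit height, so autosomal third positions (x5) are
partially saturated and X third positions (x3 overall, x20 at position 3)
are fully saturated - the regime in which third-position exclusion is the
appropriate correction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import Alignment, write_fasta
from .conflict import deep_focal_edges
from .linkage import CoverageTable
from .qc import LocusRecord
from . import trees as T
from .substitution import GTRModel, simulate_alignment

#: base frequencies / exchangeabilities loosely typical of insect
#: protein-coding nuclear loci
DEFAULT_FREQS = (0.30, 0.20, 0.22, 0.28)
DEFAULT_RATES = (1.3, 3.8, 0.9, 1.1, 4.2, 1.0)


@dataclass
class SimConfig:
    """Generator configuration; defaults define the ``faster_x_demo``
    preset (all rate multipliers are relative to a locus' base rate)."""

    n_taxa: int = 16
    n_autosomal_loci: int = 200
    n_x_loci: int = 15
    length_range: tuple[int, int] = (600, 600)      # bp, rounded to codons
    base_rate_median: float = 0.15  # subs/site per unit tree height (A loci)
    base_rate_sigma: float = 0.3    # lognormal sigma across loci
    x_rate_multiplier: float = 3.0
    third_pos_multiplier_x: float = 20.0
    third_pos_multiplier_a: float = 5.0
    gamma_alpha: float = 0.8
    grove_topologies: int = 1       # number of planted gene-tree clusters
    grove_proportions: tuple = ()   # defaults to uniform
    grove_separation_nni: int = 6   # NNI moves between planted topologies
    nni_noise: float = 0.0          # mean per-locus NNI moves (Poisson)
    n_contaminants: int = 0
    n_long_branches: int = 0
    long_branch_scale: float = 100.0
    missing_taxon_prob: float = 0.05   # chance a taxon is absent at a locus
    male_x_missing_boost: float = 0.15
    depth_mean: float = 100.0
    depth_dispersion: float = 200.0    # negative-binomial size parameter
    male_x_depth_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if min(self.x_rate_multiplier, self.third_pos_multiplier_x,
               self.third_pos_multiplier_a) <= 0:
            raise ValueError("rate multipliers must be > 0")


def preset(name: str, **overrides) -> SimConfig:
    """Named study-condition presets."""
    presets = {
        # the central faster-X + saturation demonstration
        "faster_x_demo": {},
        # clean loci + injected contaminants / long branches for QC tests;
        # enough taxa that a stretched terminal clears 50x the mean edge
        "contamination_demo": dict(n_taxa=60, n_autosomal_loci=40,
                                   n_x_loci=0, length_range=(300, 300),
                                   n_contaminants=8, n_long_branches=4,
                                   missing_taxon_prob=0.0),
        # well-separated planted topology clusters for grove recovery
        "groves_demo": dict(n_autosomal_loci=188, n_x_loci=12,
                            grove_topologies=3, grove_separation_nni=14,
                            nni_noise=1.0, length_range=(450, 450)),
        # larger locus panel for coverage-based classification
        "coverage_demo": dict(n_autosomal_loci=900, n_x_loci=100),
        # no depth structure at all (type-I error of the linkage test)
        "null_coverage": dict(n_autosomal_loci=900, n_x_loci=100,
                              male_x_depth_ratio=1.0),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {sorted(presets)}")
    cfg = {**presets[name], **overrides}
    return SimConfig(**cfg)


# -- species tree --------------------------------------------------------

def simulate_species_tree(config: SimConfig,
                          rng: np.random.Generator | None = None):
    """Birth-death species tree rescaled to height 1 (ultrametric),
    deterministic under the config seed."""
    if config.n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = rng or np.random.default_rng(config.seed)
    import random as _random
    from dendropy.model import birthdeath
    taxa = [f"T{i + 1:02d}" for i in range(config.n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.2, num_extant_tips=config.n_taxa,
        taxon_namespace=tns, rng=_random.Random(int(rng.integers(2 ** 31))))
    tree.is_rooted = False
    tree.seed_node.edge.length = None  # drop the root stem edge

    def _depth(nd):
        d = 0.0
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return d

    height = max(_depth(lf) for lf in tree.leaf_node_iter())
    for e in tree.edges():
        if e.length is not None:
            e.length /= height
    # shuffle label assignment so clade identity is seed-dependent only
    labels = taxa.copy()
    rng.shuffle(labels)
    for lf, lab in zip(tree.leaf_node_iter(), labels):
        lf.taxon.label = lab
    for nd in tree.preorder_internal_node_iter():
        nd.label = "100"
    return T.read_newick(T.write_newick(tree))


def _random_nni(tree, rng, n_moves: int):
    for _ in range(n_moves):
        nbs = T.nni_neighbors(tree)
        if not nbs:
            return tree
        tree = nbs[int(rng.integers(len(nbs)))]
    return tree


# -- locus set -----------------------------------------------------------

@dataclass
class TruthTables:
    linkage: pd.Series                 # locus -> 'A'/'X'
    grove: pd.Series                   # locus -> planted grove id (1..g)
    contaminants: pd.DataFrame         # locus, donor, recipient
    long_branches: pd.DataFrame        # locus, taxon, scale
    sex: pd.Series                     # taxon -> 'male'/'female'
    focal_split: frozenset | None = None  # deepest species-tree split


def simulate_locus_set(config: SimConfig, species_tree=None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[LocusRecord], TruthTables]:
    """Generate the full locus set plus ground-truth tables.

    Per locus: a grove topology is chosen by the mixing proportions and
    NNI noise applied; branch lengths are the species-tree lengths scaled
    by the locus base rate (and the X multiplier for X loci); the
    codon-structured alignment is simulated with per-position rate
    multipliers; contaminants, long-branch paralogs and missing taxa are
    injected afterwards and recorded.
    """
    rng = rng or np.random.default_rng(config.seed)
    if species_tree is None:
        species_tree = simulate_species_tree(config, rng=rng)
    taxa = sorted(T.leaf_labels(species_tree))
    sex = pd.Series({t: ("male" if i % 2 == 0 else "female")
                     for i, t in enumerate(taxa)})

    # planted grove topologies
    groves = [T.clone(species_tree)]
    for _ in range(config.grove_topologies - 1):
        groves.append(_random_nni(T.clone(species_tree), rng,
                                  config.grove_separation_nni))
    props = np.asarray(config.grove_proportions or
                       [1 / len(groves)] * len(groves), float)
    if abs(props.sum() - 1) > 1e-9 or len(props) != len(groves):
        raise ValueError("grove proportions must match topologies and sum to 1")

    # candidate donor->recipient pairs for contamination: distant taxa
    # only (the screen's concatenation-distance gate deliberately spares
    # close relatives, so that is where cross-contamination is plantable)
    pat = T.patristic_distances(species_tree)
    distant_pairs = [pair for pair, d in pat.items() if d >= 1.8]
    if not distant_pairs:  # shallow tree: fall back to the deepest quartile
        cut = np.percentile(list(pat.values()), 75)
        distant_pairs = [pair for pair, d in pat.items() if d >= cut]

    n_total = config.n_autosomal_loci + config.n_x_loci
    ids = [f"L{i + 1:04d}" for i in range(n_total)]
    is_x = np.zeros(n_total, bool)
    is_x[rng.choice(n_total, size=config.n_x_loci, replace=False)] = True

    # artifact injection plan
    cont_rows, lb_rows = [], []
    cont_loci = rng.choice(n_total, size=min(config.n_contaminants, n_total),
                           replace=False) if config.n_contaminants else []
    lb_pool = [i for i in range(n_total) if i not in set(np.atleast_1d(
        cont_loci).tolist())]
    lb_loci = rng.choice(lb_pool, size=min(config.n_long_branches,
                                           len(lb_pool)),
                         replace=False) if config.n_long_branches else []

    records = []
    grove_ids = np.zeros(n_total, int)
    for i, locus_id in enumerate(ids):
        lrng = np.random.default_rng(rng.integers(2 ** 31))
        g = int(lrng.choice(len(groves), p=props))
        grove_ids[i] = g + 1
        gt = T.clone(groves[g])
        if config.nni_noise > 0:
            gt = _random_nni(gt, lrng, int(lrng.poisson(config.nni_noise)))
        base = config.base_rate_median * float(
            np.exp(lrng.normal(0.0, config.base_rate_sigma)))
        if is_x[i]:
            base *= config.x_rate_multiplier
            pos3 = config.third_pos_multiplier_x
        else:
            pos3 = config.third_pos_multiplier_a
        for e in gt.edges():
            if e.length is not None:
                e.length *= base

        lb_taxon = None
        if i in set(np.atleast_1d(lb_loci).tolist()):
            # paralog emulation: terminal stretched to `scale` times the
            # mean edge (detectable only when the tree has enough edges
            # that one outlier cannot dominate the mean itself)
            lb_taxon = taxa[int(lrng.integers(len(taxa)))]
            nd = gt.find_node_with_taxon_label(lb_taxon)
            nd.edge.length = config.long_branch_scale * T.mean_branch_length(gt)
            lb_rows.append({"locus": locus_id, "taxon": lb_taxon,
                            "scale": config.long_branch_scale})

        lo, hi = config.length_range
        length = 3 * int(lrng.integers(lo // 3, hi // 3 + 1))
        model = GTRModel(freqs=DEFAULT_FREQS, rates=DEFAULT_RATES,
                         alpha=config.gamma_alpha)
        # normalise codon-position multipliers to mean 1 so gene-tree
        # branch lengths stay in substitutions/site for the whole locus
        mult = np.array([1.0, 1.0, pos3])
        aln = simulate_alignment(gt, model, length,
                                 site_rate_multipliers=mult / mult.mean(),
                                 rng=lrng)
        aln = aln.select_taxa([t for t in taxa if t in aln])

        # cross-contamination: recipient sequence becomes a near-copy of
        # the donor's, and the gene tree reflects it (recipient regrafted
        # as the donor's sister), as tree estimation would recover
        if i in set(np.atleast_1d(cont_loci).tolist()):
            pair = distant_pairs[int(lrng.integers(len(distant_pairs)))]
            donor, recipient = (pair if lrng.random() < 0.5
                                else pair[::-1])
            seqs = {t: aln.sequence(t) for t in aln.taxa}
            src = list(seqs[donor])
            mutate = lrng.random(len(src)) < 0.002
            for k in np.where(mutate)[0]:
                src[k] = "ACGT"[int(lrng.integers(4))]
            seqs[recipient] = "".join(src)
            aln = Alignment(list(seqs), [seqs[t] for t in seqs],
                            codon_frame=aln.codon_frame)
            gt = _regraft_as_sister(gt, mobile=recipient, target=donor)
            cont_rows.append({"locus": locus_id, "donor": donor,
                              "recipient": recipient})

        # missing data: whole-taxon absence, boosted for male X loci
        drop = []
        for t in aln.taxa:
            p = config.missing_taxon_prob
            if is_x[i] and sex[t] == "male":
                p += config.male_x_missing_boost
            if lrng.random() < p and t not in (lb_taxon,):
                drop.append(t)
        if len(aln.taxa) - len(drop) >= 6:
            for t in drop:
                aln = aln.drop_taxon(t)
                gt = T.prune_taxon(gt, t)

        records.append(LocusRecord(locus_id, aln, gt,
                                   linkage="X" if is_x[i] else "A"))

    truth = TruthTables(
        linkage=pd.Series(np.where(is_x, "X", "A"), index=ids),
        grove=pd.Series(grove_ids, index=ids),
        contaminants=pd.DataFrame(cont_rows,
                                  columns=["locus", "donor", "recipient"]),
        long_branches=pd.DataFrame(lb_rows,
                                   columns=["locus", "taxon", "scale"]),
        sex=sex,
        focal_split=(focal[0].split if (focal := deep_focal_edges(
            species_tree, 1)) else None),
    )
    return records, truth


def _regraft_as_sister(tree, mobile: str, target: str):
    """Detach leaf ``mobile`` and reattach it as sister of leaf ``target``
    on a near-zero branch (mimics a contaminant's placement)."""
    t = T.prune_taxon(tree, mobile)
    nd = t.find_node_with_taxon_label(target)
    parent = nd.parent_node
    parent.remove_child(nd)
    mid = parent.new_child(edge_length=max((nd.edge.length or 0.0) - 1e-6,
                                           1e-6))
    old_len = nd.edge.length
    mid.add_child(nd)
    nd.edge.length = 1e-6
    tx = t.taxon_namespace.new_taxon(label=mobile)
    mid.new_child(taxon=tx, edge_length=1e-6)
    return T.read_newick(T.write_newick(t))


# -- coverage ------------------------------------------------------------

def simulate_coverage(config: SimConfig, linkage_truth: pd.Series,
                      sex: pd.Series,
                      rng: np.random.Generator | None = None
                      ) -> CoverageTable:
    """Negative-binomial depth table: mean = base x sample effect x
    (male_x_depth_ratio for male samples at X loci)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    loci = list(linkage_truth.index)
    samples = list(sex.index)
    size = config.depth_dispersion
    cols = {}
    for s in samples:
        sample_eff = float(np.exp(rng.normal(0.0, 0.2)))
        mu = np.full(len(loci), config.depth_mean * sample_eff)
        if sex[s] == "male":
            mu[np.asarray(linkage_truth.values) == "X"] *= \
                config.male_x_depth_ratio
        p = size / (size + mu)
        cols[s] = rng.negative_binomial(size, p)
    depths = pd.DataFrame(cols, index=loci, dtype=float)
    return CoverageTable(depths, sex, linkage=linkage_truth)


def simulate_coverage_only(config: SimConfig, n_males: int = 5,
                           n_females: int = 5,
                           rng: np.random.Generator | None = None
                           ) -> CoverageTable:
    """Coverage table without simulating any sequence data: linkage truth
    drawn from the config locus counts, samples split by sex."""
    rng = rng or np.random.default_rng(config.seed)
    n_total = config.n_autosomal_loci + config.n_x_loci
    ids = [f"L{i + 1:04d}" for i in range(n_total)]
    is_x = np.zeros(n_total, bool)
    is_x[rng.choice(n_total, size=config.n_x_loci, replace=False)] = True
    linkage = pd.Series(np.where(is_x, "X", "A"), index=ids)
    sex = pd.Series({f"M{i + 1}": "male" for i in range(n_males)}
                    | {f"F{i + 1}": "female" for i in range(n_females)})
    return simulate_coverage(config, linkage, sex, rng=rng)


# -- fixture directory ---------------------------------------------------

def write_fixture(outdir, records, truth, species_tree, coverage=None,
                  config=None) -> None:
    """Materialise a simulated data set as plain-text files (loci/*.fasta,
    Newick trees, TSV tables, config.json)."""
    out = Path(outdir)
    (out / "loci").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for rec in records:
        write_fasta(rec.alignment, out / "loci" / f"{rec.id}.fasta")
    with open(out / "genetrees.nwk", "w") as fh:
        for rec in records:
            fh.write(T.write_newick(rec.tree).strip() + "\n")
    T.write_newick(species_tree, out / "species_tree.nwk")
    truth.linkage.rename("linkage").to_csv(out / "linkage.tsv", sep="\t",
                                           index_label="locus")
    truth.sex.rename("sex").to_csv(out / "sex.tsv", sep="\t",
                                   index_label="sample")
    truth.grove.rename("grove").to_csv(out / "truth" / "grove.tsv", sep="\t",
                                       index_label="locus")
    truth.contaminants.to_csv(out / "truth" / "contaminants.tsv", sep="\t",
                              index=False)
    truth.long_branches.to_csv(out / "truth" / "long_branches.tsv", sep="\t",
                               index=False)
    if coverage is not None:
        coverage.write(out / "coverage.tsv", out / "sex.tsv",
                       out / "linkage.tsv")
    if config is not None:
        (out / "config.json").write_text(
            json.dumps(asdict(config), indent=2, default=str) + "\n")


def load_fixture(indir) -> tuple[list[LocusRecord], "dendropy.Tree",
                                 pd.Series, pd.Series]:
    """Read back a fixture directory written by :func:`write_fixture`:
    (records, species_tree, linkage, sex). Gene-tree lines pair with the
    locus FASTA files in sorted id order."""
    from .alignment import read_fasta
    ind = Path(indir)
    fastas = sorted((ind / "loci").glob("*.fasta"))
    gene_lines = [l for l in (ind / "genetrees.nwk").read_text().splitlines()
                  if l.strip()]
    if len(fastas) != len(gene_lines):
        raise ValueError(f"{ind}: {len(fastas)} loci but "
                         f"{len(gene_lines)} gene trees")
    linkage = pd.read_csv(ind / "linkage.tsv", sep="\t",
                          index_col=0).iloc[:, 0]
    sex = pd.read_csv(ind / "sex.tsv", sep="\t", index_col=0).iloc[:, 0]
    records = []
    for fp, nwk in zip(fastas, gene_lines):
        locus_id = fp.stem
        aln = read_fasta(fp)
        if aln.length % 3 == 0:
            aln = Alignment(aln.taxa, [aln.sequence(t) for t in aln.taxa],
                            codon_frame=True)
        records.append(LocusRecord(locus_id, aln, T.read_newick(nwk),
                                   linkage=str(linkage.get(locus_id,
                                                           "unknown"))))
    species_tree = T.read_newick(ind / "species_tree.nwk")
    return records, species_tree, linkage, sex
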