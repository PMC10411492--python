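"""Per-locus property profiling.

Summary statistics used to contrast autosomal and X-linked loci: basic
matrix stats, parsimony-informative fraction, GC content per codon
position, tree-derived rates, a saturation slope, a phylogenetic
informativeness profile, and pairwise dN/dS (Nei-Gojobori 1986).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment
from . import trees as T
from .substitution import jc_distance_from_p, p_distance_matrix

# -- matrix statistics ---------------------------------------------------


def parsimony_informative_proportion(aln: Alignment) -> float:
    """Fraction of columns with >= 2 states each present in >= 2 taxa."""
    codes = aln.codes()
    n_inf = 0
    for col in codes.T:
        col = col[col < 4]
        if col.size < 4:
            continue
        counts = np.bincount(col, minlength=4)
        if (counts >= 2).sum() >= 2:
            n_inf += 1
    return n_inf / aln.length


def gc_by_codon_position(aln: Alignment) -> dict[str, float]:
    """Mean and across-taxon variance of per-taxon GC content at each
    codon position (ignoring gaps/N)."""
    if aln.length % 3 != 0:
        raise ValueError("GC-by-position requires a codon-framed alignment")
    mat = aln.matrix
    out = {}
    pos = np.arange(aln.length) % 3
    for p in range(3):
        sub = mat[:, pos == p]
        valid = (sub != "-") & (sub != "N")
        gc = (sub == "G") | (sub == "C")
        with np.errstate(invalid="ignore"):
            per_taxon = np.where(valid.sum(1) > 0,
                                 gc.sum(1) / np.maximum(valid.sum(1), 1),
                                 np.nan)
        out[f"gc{p + 1}_mean"] = float(np.nanmean(per_taxon))
        out[f"gc{p + 1}_var"] = float(np.nanvar(per_taxon))
    return out


# -- saturation ----------------------------------------------------------

def saturation_slope(aln: Alignment, tree) -> float:
    """Slope of the zero-intercept regression of uncorrected p-distance on
    patristic distance over all taxon pairs.

    Near 1 for unsaturated loci; decays toward 0 as multiple hits
    accumulate (p-distance is bounded by 3/4). NaN when the tree carries
    no patristic variation.
    """
    taxa = [t for t in aln.taxa if t in T.leaf_labels(tree)]
    if len(taxa) < 4:
        raise ValueError("saturation_slope needs >= 4 shared taxa")
    sub = aln.select_taxa(taxa)
    pmat = p_distance_matrix(sub)
    pat = T.patristic_distances(T.restrict_to_taxa(tree, taxa))
    xs, ys = [], []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        key = tuple(sorted((taxa[i], taxa[j])))
        if key in pat and np.isfinite(pmat[i, j]):
            xs.append(pat[key])
            ys.append(pmat[i, j])
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.size == 0 or np.all(xs == 0):
        return float("nan")
    return float((xs @ ys) / (xs @ xs))


# -- phylogenetic informativeness ----------------------------------------

@dataclass
class InformativenessProfile:
    epochs: np.ndarray       # normalised time grid on [0, 1]
    curve: np.ndarray        # summed per-site informativeness
    epoch_of_max: float      # NaN when the curve is identically zero
    area: float              # trapezoid integral over the grid


def informativeness_profile(site_rates, step: float = 0.01
                            ) -> InformativenessProfile:
    """Townsend-style informativeness summed over sites on a 0..1 grid.

    Each site of rate r contributes ``16 r^2 t exp(-4 r t)`` at epoch t
    (tree height normalised to 1); the profile is sampled at ``step``
    intervals, the maximising epoch taken on the grid, and the area
    computed by the trapezoid rule.
    """
    rates = np.asarray(site_rates, float)
    if np.any(rates < 0):
        raise ValueError("site rates must be non-negative")
    epochs = np.arange(0.0, 1.0 + step / 2, step)
    curve = (16.0 * rates[:, None] ** 2 * epochs[None, :]
             * np.exp(-4.0 * rates[:, None] * epochs[None, :])).sum(axis=0)
    if np.all(curve == 0):
        emax = float("nan")
    else:
        emax = float(epochs[int(np.argmax(curve))])
    area = float(np.trapezoid(curve, epochs))
    return InformativenessProfile(epochs, curve, emax, area)


# -- NG86 pairwise dN/dS -------------------------------------------------

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
# standard genetic code in TCAG order
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_TABLE = dict(zip(_CODONS, _AA))
STOPS = {c for c, a in CODON_TABLE.items() if a == "*"}


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are
    synonymous (changes to stop codons count as nonsynonymous)."""
    aa = CODON_TABLE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if CODON_TABLE[alt] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts between
    two codons (all substitution orders; paths through stops excluded
    unless every path is blocked)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0.0, 0.0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS:
                blocked = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


@dataclass
class DnDsResult:
    dn: float
    ds: float
    ratio: float        # NaN when dS == 0
    sd: float           # raw synonymous differences
    nd: float           # raw nonsynonymous differences
    s_sites: float
    n_sites: float
    n_codons: int
    saturated: bool = False


def dnds_pairwise(aln: Alignment, taxon1: str, taxon2: str) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    Codons containing gaps, ``N`` or stop codons in either sequence are
    skipped. The ratio is NaN when dS = 0; pS or pN >= 3/4 flags the
    comparison as saturated (the corresponding distance is infinite).
    """
    if aln.length % 3 != 0:
        raise ValueError("dnds_pairwise requires a codon-framed alignment")
    s1, s2 = aln.sequence(taxon1), aln.sequence(taxon2)
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if (set(c1 + c2) - set("ACGT")) or c1 in STOPS or c2 in STOPS:
            continue
        n_codons += 1
        s_a, n_a = _codon_sites(c1)
        s_b, n_b = _codon_sites(c2)
        S += (s_a + s_b) / 2
        N += (n_a + n_b) / 2
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = jc_distance_from_p(ps)
    dn = jc_distance_from_p(pn)
    saturated = not (math.isfinite(ds) and math.isfinite(dn))
    ratio = dn / ds if (math.isfinite(ds) and ds > 0
                        and math.isfinite(dn)) else float("nan")
    return DnDsResult(dn, ds, ratio, Sd, Nd, S, N, n_codons, saturated)


# -- combined per-locus table --------------------------------------------

PROPERTY_COLUMNS = ["id", "linkage", "length_bp", "n_taxa", "missing_prop",
                    "pis_prop", "gc1_mean", "gc1_var", "gc2_mean", "gc2_var",
                    "gc3_mean", "gc3_var", "tree_length", "mean_brlen",
                    "mean_support", "sat_slope", "pi_epoch_max", "pi_area"]


def locus_properties(record, site_rates=None) -> dict:
    """Property row for one locus record (see ``PROPERTY_COLUMNS``).

    Informativeness fields are filled only when per-site rates are given.
    """
    aln, tree = record.alignment, record.tree
    row = {"id": record.id, "linkage": record.linkage,
           "length_bp": aln.length, "n_taxa": aln.n_taxa,
           "missing_prop": aln.missing_proportion(),
           "pis_prop": parsimony_informative_proportion(aln)}
    if aln.length % 3 == 0:
        row.update(gc_by_codon_position(aln))
    else:
        row.update({f"gc{p}_{k}": float("nan")
                    for p in (1, 2, 3) for k in ("mean", "var")})
    row["tree_length"] = T.tree_length(tree)
    row["mean_brlen"] = T.mean_branch_length(tree)
    ms = T.mean_support(tree)
    row["mean_support"] = float("nan") if ms is None else ms
    try:
        row["sat_slope"] = saturation_slope(aln, tree)
    except ValueError:
        row["sat_slope"] = float("nan")
    if site_rates is not None:
        prof = informativeness_profile(site_rates)
        row["pi_epoch_max"] = prof.epoch_of_max
        row["pi_area"] = prof.area
    else:
        row["pi_epoch_max"] = float("nan")
        row["pi_area"] = float("nan")
    record.properties.update(row)
    return row


def properties_table(records, site_rates_by_locus=None) -> pd.DataFrame:
    rows = []
    for rec in records:
        rates = (site_rates_by_locus or {}).get(rec.id)
        rows.append(locus_properties(rec, site_rates=rates))
    return pd.DataFrame(rows, columns=PROPERTY_COLUMNS)
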