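"""Bookkeeping over the reference study's dataset summary counts.

``data/dataset_counts.tsv`` holds the published summary dimensions of a
large assassin-bug (Reduvioidea) phylogenomic dataset assembled from
anchored hybrid enrichment and orthology-mined loci, split by chromosomal
linkage against triatomine chromosome-level reference assemblies. The
helpers here derive the combined-matrix dimensions and linkage
proportions that downstream summaries are sanity-checked against.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .conflict import GroveAssignment, grove_composition


def load_dataset_counts() -> pd.DataFrame:
    with resources.files("xgrove.data").joinpath(
            "dataset_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def bookkeeping_summary(counts: pd.DataFrame | None = None) -> dict:
    """Derived dataset bookkeeping: combined dimensions, X-linkage
    proportion (via the grove-composition op on a single all-locus
    grove), and the autosome:X locus ratio."""
    c = counts if counts is not None else load_dataset_counts()
    n_loci = int(c.loc["ahe", "n_loci"] + c.loc["omcl", "n_loci"])
    nt = int(c.loc["ahe", "nt_positions"] + c.loc["omcl", "nt_positions"])
    n_x = int(c.loc["x", "n_loci"])
    n_au = int(c.loc["autosomal", "n_loci"])
    assert n_x + n_au == n_loci, "linkage split does not cover the dataset"
    au_nt = int(nt - c.loc["x", "nt_positions"])

    linkage = pd.Series(["X"] * n_x + ["A"] * (n_loci - n_x),
                        index=[f"L{i}" for i in range(n_loci)])
    one_grove = GroveAssignment(labels=np.ones(n_loci, int),
                                coordinates=np.zeros((n_loci, 1)),
                                eigenvalues=np.array([]),
                                locus_ids=list(linkage.index))
    comp = grove_composition(one_grove, linkage).set_index("grove")

    return {
        "combined_locus_count": n_loci,
        "combined_nt_positions": nt,
        "combined_aa_positions": nt // 3,
        "autosomal_locus_count": n_loci - n_x,
        "autosomal_nt_positions": au_nt,
        "x_locus_count": n_x,
        "x_fraction_pct": float(comp.loc["TOTAL", "pct_X_rounded"]),
        "au_to_x_locus_ratio": (n_loci - n_x) / n_x,
    }
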