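"""Read-depth confirmation of X-linkage from sexed samples.

On a hemizygous X, males carry one copy where females carry two, so
X-linked loci show roughly half the normalised read depth in males. The
module normalises a locus x sample depth table by each sample's median
autosomal depth, tests the male-X deficit at the group level (rank-sum,
loci as units), and scores each locus by its median male:female log2
depth ratio (about -1 for X-linked, about 0 for autosomal).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class LinkageError(ValueError):
    pass


@dataclass
class CoverageTable:
    """Mean read depth per locus (rows) and sample (columns), with sample
    sex labels and, optionally, reference per-locus linkage labels."""

    depths: pd.DataFrame                  # loci x samples, >= 0
    sex: pd.Series                        # sample -> 'male'/'female'/'unknown'
    linkage: pd.Series | None = None      # locus -> 'A'/'X'
    normalized: bool = False

    def __post_init__(self):
        if (self.depths.values < 0).any():
            raise LinkageError("negative depths")
        missing = set(self.depths.columns) - set(self.sex.index)
        if missing:
            raise LinkageError(f"samples without sex label: {sorted(missing)}")

    def samples_of_sex(self, sex: str) -> list[str]:
        return [s for s in self.depths.columns if self.sex.get(s) == sex]

    # -- I/O (TSV: first column locus id, header row = sample ids) -------
    @classmethod
    def read(cls, depths_tsv, sex_tsv, linkage_tsv=None) -> "CoverageTable":
        depths = pd.read_csv(depths_tsv, sep="\t", index_col=0)
        sex = pd.read_csv(sex_tsv, sep="\t", index_col=0).iloc[:, 0]
        linkage = None
        if linkage_tsv is not None:
            linkage = pd.read_csv(linkage_tsv, sep="\t", index_col=0).iloc[:, 0]
        return cls(depths, sex, linkage)

    def write(self, depths_tsv, sex_tsv, linkage_tsv=None) -> None:
        self.depths.to_csv(depths_tsv, sep="\t", index_label="locus")
        self.sex.rename("sex").to_csv(sex_tsv, sep="\t", index_label="sample")
        if linkage_tsv is not None and self.linkage is not None:
            self.linkage.rename("linkage").to_csv(
                linkage_tsv, sep="\t", index_label="locus")


def normalize_depths(table: CoverageTable) -> CoverageTable:
    """Divide each sample's depths by that sample's median autosomal depth
    (per-sample library-size correction); all-zero samples are dropped."""
    if table.linkage is None:
        raise LinkageError("normalisation requires reference linkage labels")
    auto = table.linkage[table.linkage == "A"].index
    auto = [l for l in auto if l in table.depths.index]
    norm = {}
    for s in table.depths.columns:
        med = float(table.depths.loc[auto, s].median())
        if med <= 0:
            warnings.warn(f"sample {s}: zero median autosomal depth; dropped")
            continue
        norm[s] = table.depths[s] / med
    return CoverageTable(pd.DataFrame(norm), table.sex, table.linkage,
                         normalized=True)


@dataclass
class LinkageTestResult:
    """Group-level male-X depth deficit tests (loci as units)."""

    p_male_x_vs_female_x: float
    p_male_x_vs_male_a: float
    effect_male_x_vs_female_x: float   # median log2 ratio
    effect_male_x_vs_male_a: float
    n_x: int
    n_a: int
    scores: pd.DataFrame | None = None  # per-locus linkage scores

    def summary(self) -> dict:
        return {k: getattr(self, k) for k in
                ("p_male_x_vs_female_x", "p_male_x_vs_male_a",
                 "effect_male_x_vs_female_x", "effect_male_x_vs_male_a",
                 "n_x", "n_a")}

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _sex_medians(table: CoverageTable) -> pd.DataFrame:
    males = table.samples_of_sex("male")
    females = table.samples_of_sex("female")
    return pd.DataFrame({
        "male": table.depths[males].median(axis=1) if males else np.nan,
        "female": table.depths[females].median(axis=1) if females else np.nan,
    })


def group_depth_test(table: CoverageTable, alpha: float = 0.05
                     ) -> LinkageTestResult:
    """One-sided rank-sum tests for the male-X coverage deficit.

    Units are loci: each locus contributes its median normalised depth per
    sex. Tested one-sided: median male depth of X loci below (a) median
    female depth of X loci and (b) median male depth of autosomal loci.
    """
    if not table.normalized:
        table = normalize_depths(table)
    if len(table.samples_of_sex("male")) < 2 or \
            len(table.samples_of_sex("female")) < 2:
        raise LinkageError("need >= 2 samples of each sex")
    med = _sex_medians(table)
    is_x = table.linkage.reindex(table.depths.index) == "X"
    mx = med.loc[is_x, "male"].dropna()
    fx = med.loc[is_x, "female"].dropna()
    ma = med.loc[~is_x, "male"].dropna()
    with np.errstate(divide="ignore"):
        eff_sex = float(np.nanmedian(np.log2(mx.values / fx.values)))
        eff_chrom = float(np.log2(np.median(mx) / np.median(ma)))
    p1 = stats.mannwhitneyu(mx, fx, alternative="less").pvalue \
        if len(mx) and len(fx) else np.nan
    p2 = stats.mannwhitneyu(mx, ma, alternative="less").pvalue \
        if len(mx) and len(ma) else np.nan
    return LinkageTestResult(float(p1), float(p2), eff_sex, eff_chrom,
                             int(is_x.sum()), int((~is_x).sum()),
                             scores=per_locus_linkage_score(table))


def per_locus_linkage_score(table: CoverageTable, threshold: float = -0.5
                            ) -> pd.DataFrame:
    """Per-locus log2(male/female median normalised depth) and the derived
    predicted_X / predicted_A call at ``threshold`` (NaN score when the
    female depth is zero)."""
    if not table.normalized:
        table = normalize_depths(table)
    med = _sex_medians(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2(med["male"].values / med["female"].values)
    score = np.where(med["female"].values > 0, score, np.nan)
    out = pd.DataFrame({"locus": table.depths.index,
                        "score": score}).set_index("locus")
    out["call"] = np.where(np.isnan(score), "undefined",
                           np.where(score < threshold,
                                    "predicted_X", "predicted_A"))
    if table.linkage is not None:
        out["reference"] = table.linkage.reindex(out.index)
    return out


def classification_metrics(scores: pd.DataFrame) -> dict:
    """Accuracy and Jaccard agreement of predicted_X against the reference
    linkage labels."""
    df = scores.dropna(subset=["score"])
    truth_x = df["reference"] == "X"
    pred_x = df["call"] == "predicted_X"
    acc = float(np.mean(truth_x == pred_x))
    union = (truth_x | pred_x).sum()
    jac = float((truth_x & pred_x).sum() / union) if union else 1.0
    return {"accuracy": acc, "jaccard_x": jac, "n": int(len(df))}
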