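"""Generate a chromosome-aware synthetic phylogenomic dataset.

Builds the default fast-X study preset: 16 taxa, 200 autosomal + 15
X-linked loci of 600 bp, X loci evolving 3x faster with heavily saturated
third codon positions, plus a sexed coverage table in which male X loci
sit at half depth.
"""

import numpy as np

import xgrove as xg
from xgrove import trees as T

cfg = xg.preset("faster_x_demo", seed=7)
rng = np.random.default_rng(cfg.seed)
species_tree = xg.simulate_species_tree(cfg, rng=rng)
records, truth = xg.simulate_locus_set(cfg, species_tree=species_tree,
                                       rng=rng)
coverage = xg.simulate_coverage(cfg, truth.linkage, truth.sex)

n_x = int((truth.linkage == "X").sum())
print(f"species tree: {len(T.leaf_labels(species_tree))} taxa, height 1")
print(f"loci: {len(records)} total, {n_x} X-linked")
tl = {"A": [], "X": []}
for rec in records:
    tl[rec.linkage].append(T.tree_length(rec.tree))
print(f"mean gene-tree length: A={np.mean(tl['A']):.2f} "
      f"X={np.mean(tl['X']):.2f} substitutions/site "
      f"(ratio ~ the faster-X multiplier, {cfg.x_rate_multiplier})")
print(f"coverage table: {coverage.depths.shape[0]} loci x "
      f"{coverage.depths.shape[1]} sexed samples")
# The truth tables (linkage, grove, injected artifacts) are what the
# QC/linkage/conflict stages are scored against in the tests.
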