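"""Per-base likelihood signal and the third-codon-position correction.

For a small fast-X locus panel, scores each locus' support for the
reference resolution of the deepest species-tree edge against the best
nearest-neighbour-interchange alternative (delta lnL per base), bins the
signal by chromosomal linkage, and repeats the analysis after excluding
third codon positions (NT12). Saturated X third positions dilute or
invert the X signal; NT12 brings the X bin back in line with the
autosomes.
"""

import warnings

import numpy as np

import xgrove as xg
from xgrove import conflict as C
from xgrove.substitution import fit_model

warnings.filterwarnings("ignore")

cfg = xg.preset("faster_x_demo", n_autosomal_loci=25, n_x_loci=8, seed=2)
rng = np.random.default_rng(cfg.seed)
st = xg.simulate_species_tree(cfg, rng=rng)
records, truth = xg.simulate_locus_set(cfg, species_tree=st, rng=rng)
edges = [C.FocalEdge("deep", truth.focal_split)]

for tag, recs in (("full NT123", records),
                  ("NT12 corrected", C.nt12_correction(records))):
    models = {r.id: fit_model(r.alignment, r.tree) for r in recs}
    sig = C.signal_table(recs, st, edges, models=models)
    _, regimes = C.bin_signal(sig)
    row = regimes.iloc[0]
    print(f"{tag:15s} median delta lnL/bp: A = {row['median_A']:+.4f}, "
          f"X = {row['median_X']:+.4f}  -> {row['regime']}")
print("(positive = the locus bin favours the reference resolution; the "
      "X bin\nshould move toward the autosomal bin once third positions "
      "are excluded)")
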