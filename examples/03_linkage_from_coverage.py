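"""Confirm X-linkage from read depth of sexed samples.

On a hemizygous X chromosome males carry one copy, so after per-sample
normalisation male X-linked loci sit near half depth: a per-locus
log2(male/female) score of about -1, against about 0 for autosomes.
"""

import xgrove as xg

cov = xg.simulate_coverage_only(xg.preset("coverage_demo", seed=11),
                                n_males=5, n_females=5)
res = xg.group_depth_test(cov)

print("group tests (loci as units, one-sided rank-sum):")
print(f"  male-X < female-X: p = {res.p_male_x_vs_female_x:.3g}, "
      f"median log2 ratio = {res.effect_male_x_vs_female_x:+.2f}")
print(f"  male-X < male-A:   p = {res.p_male_x_vs_male_a:.3g}, "
      f"median log2 ratio = {res.effect_male_x_vs_male_a:+.2f}")
m = xg.classification_metrics(res.scores)
print(f"per-locus calls at score < -0.5: accuracy {100*m['accuracy']:.1f}%"
      f", Jaccard(X) {m['jaccard_x']:.2f} over {m['n']} loci")
print("(a log2 ratio near -1 is the expected one-copy/two-copy deficit)")
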