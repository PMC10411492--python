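# Methods

This note documents the models and procedures implemented in `xgrove`,
the calibration of the synthetic-data generator, and the numerical and
design choices made where more than one reasonable option existed.

## Substitution model and likelihood

All sequence-level computation uses a general time-reversible (GTR)
nucleotide model with empirical base frequencies, exchangeabilities in
the order AC, AG, AT, CG, CT, GT (GT fixed to 1), and optional discrete
gamma rate heterogeneity. The rate matrix is normalised to one expected
substitution per site per unit branch length, and discrete-gamma
category rates are means of equal-probability bins (4 categories by
default), renormalised to mean exactly 1 — so branch lengths are in
substitutions/site everywhere.

Transition probabilities come from the spectral decomposition of the
symmetrised rate matrix; eigenvalue noise is clipped at zero so that
arbitrarily long branches stay finite. Log-likelihoods use Felsenstein
pruning over compressed site patterns with per-pattern rescaling at each
internal node, which keeps the computation exact in log space (the
pruning value matches exhaustive enumeration over internal-state
assignments to 1e-8 on small fixtures, and is invariant to root
placement under reversibility). Gaps and `N` are fully ambiguous
(all-ones tip partials); a wholly missing taxon therefore marginalises
out exactly.

Branch lengths on a fixed topology are optimised coordinate-wise: each
sweep recomputes inside partials post-order, then walks the tree
pre-order maintaining outside partials and applying Brent's method to
each branch on the log scale (tolerance 1e-3 on log-length, branches
clamped to [1e-8, 20]). Within a sweep the outside partials of
already-visited sibling subtrees can be one update stale; the sweep is
therefore accepted only if it improves the exactly recomputed
log-likelihood, and rolled back otherwise, making the reported value
non-decreasing across sweeps. Default stopping: improvement < 1e-4 or 20
sweeps; the conflict analysis uses a looser 1e-2 / 4-sweep setting,
which changes per-edge Δ lnL by far less than the bin medians it feeds.

Per-locus model fitting estimates frequencies from counts,
exchangeabilities by a moment estimator on pairwise mismatch counts
(optionally refined by Nelder–Mead ML), and the gamma shape jointly with
a global branch-scale factor by Nelder–Mead on the given gene tree. The
fitted model is then held fixed across the NNI topologies of that locus,
isolating topological signal from model re-fitting; model estimation is
per locus rather than shared across loci.

Pairwise distances: Jukes–Cantor by closed form (saturated p ≥ 3/4
returns an infinite sentinel), GTR by one-dimensional ML on the pair's
count matrix under the alignment-wide empirical model. The GTR estimator
is deliberately gamma-free, matching common practice for quick
concatenation-level screens; on deeply diverged, rate-heterogeneous data
it mildly underestimates large distances, which is acceptable for the
thresholded uses it serves here.

## Locus hygiene

* **Long branches**: terminal edges > factor (default 50) times the mean
  over *all* edges, outlier included, iterated to a fixed point because
  removal changes the mean. With E edges, a single outlier of relative
  size s is detectable only when s > f(E−1)/(E−f); at factor 50 this
  requires more than ~50 edges, so the rule is intentionally insensitive
  on small trees (the generator's QC preset uses 60 taxa for this
  reason).
* **Cross-contamination**: pairs with within-locus GTR distance < 0.01
  but concatenation-level distance > 0.2 are suspects (the second gate
  spares genuinely similar close relatives). For each suspect pair the
  gene tree is compared to the species tree after dropping each member;
  the drop giving the strictly smaller RF identifies the contaminant
  (removed; the other member is the donor and is kept), and an exact tie
  removes both. Multi-taxon groups are handled pairwise in sorted taxon
  order. A cheap p-distance prescreen avoids ML fits for the vast
  majority of pairs.
* **Distance outliers**: sequences whose mean JC distance to all others
  exceeds mean + k·SD (k = 3), iterated to a fixed point. Iteration (a
  projection) was chosen over a single pass so that the full cascade is
  idempotent — a property the test suite asserts — at the cost of a
  slightly higher trim rate on clean data (well under 1% of sequences in
  the acceptance conditions).
* **Short loci**: strictly shorter than 150 bp dropped; exactly 150 bp
  retained.
* **RF-outlier loci**: gene-tree wRF to the species tree, normalised by
  the summed internal branch length of both restricted trees, with a
  Tukey fence (Q3 + 1.5·IQR). Fewer than 8 loci: no filtering, warning.

The wRF distance is the linear branch-score variant: the sum over the
union of non-trivial splits of |w₁ − w₂|, absent splits contributing
their full weight, computed after restricting both trees to shared
leaves. Support collapsing contracts internal edges with numeric support
strictly below the threshold; edges without a support value are never
collapsed.

## Locus properties

Length, taxon count, missing proportion, parsimony-informative fraction
(≥ 2 states each in ≥ 2 taxa), per-codon-position GC mean and
across-taxon variance, tree length, mean branch length, mean support. A
saturation slope is the zero-intercept regression of pairwise p-distance
on patristic distance (≈ 1 unsaturated, → 0 saturated; the method is a
standard slope diagnostic chosen here among several unstated-in-field
variants). Phylogenetic informativeness follows the Townsend profile:
each site of rate r contributes 16 r² t e^(−4rt) at normalised epoch t,
sampled at 0.01 intervals on [0, 1], with the grid argmax and trapezoid
area reported. Pairwise dN/dS is Nei–Gojobori (1986) with
pathway-averaged difference counts (paths through stop codons excluded
when any open path exists) and Jukes–Cantor correction; the ratio is a
NaN sentinel when dS = 0. NG86 was chosen over a codon-model ML fit
because the package's use of dN/dS is qualitative (X vs autosome
comparison under equal selection), where the two agree.

## Coverage-based linkage

Depths are normalised per sample by that sample's median autosomal
depth, making the autosomal median 1 and cancelling library size. The
unit of replication is the locus: each locus contributes its median
normalised depth per sex, avoiding pseudo-replication across samples.
Group tests are one-sided Mann–Whitney rank-sums (male-X < female-X;
male-X < male-autosome) with median log2-ratio effect sizes; the
per-locus score log2(male/female) is classified as X below −0.5 (half
way to the one-copy expectation of −1 on the log scale).

## Conflict signal, regimes, NT12

Focal edges are identified by the bipartition they induce, so they
survive restriction to each locus' taxon set when possible; loci in
which a focal bipartition collapses contribute no row rather than an
imputed zero. The sign convention is fixed: Δ = lnL(ref) − lnL(best NNI
alternative), positive when the reference is favoured. Binned summaries
report summed Δ (the aggregate evidence of a bin), the median and IQR of
Δ/bp, and a per-edge regime: both medians positive with X < A
(*concordant-weaker*), both positive with X ≥ A (*concordant-stronger*),
opposite signs (*discordant*), both non-positive
(*concordant-negative*). The NT12 correction applies third-position
exclusion per locus and re-runs the identical machinery; loci not in
codon frame pass through unchanged with a warning, making the correction
idempotent.

Tree-space analysis collapses nodes below 50% support, computes the full
pairwise wRF matrix (pairs sharing < 4 taxa get the matrix maximum as a
sentinel), embeds it by classical PCoA (double-centred −½JD²J,
eigendecomposition; all eigenvalues reported, negative ones diagnosing
non-Euclidean input, coordinates built from positive axes only), and
k-means-clusters loci on the axes carrying ≥ 80% of the positive
eigenvalue mass (50 restarts, fixed seed; k is user-supplied — no formal
criterion for k is imposed). Grove composition reports per-grove locus
counts and X-linked percentages plus the dataset-wide percentage, raw
and rounded.

## Synthetic data: what it emulates, and what not

The generator reproduces the statistical structure the pipeline is
designed to interrogate. Defaults (the `faster_x_demo` preset): 16 taxa,
200 autosomal + 15 X loci (≈ 7% X-linked), 600 bp codon-structured loci
on a birth–death species tree rescaled to height 1. Calibration targets
the study's regime — autosomal loci informative even at the deepest
split, X loci saturated there: autosomal base rate lognormal with median
0.15 substitutions/site per unit height
(σ = 0.3 across loci); X loci 3× faster overall; third codon positions
5× (autosomal) or 20× (X) the positions-1–2 rate, with the
position-multiplier triple normalised to mean 1 so gene-tree branch
lengths remain in substitutions/site for the whole locus. Under this
regime autosomal third positions are partially saturated and X third
positions essentially fully saturated — the regime in which
third-position exclusion is the appropriate correction, and with the
consequence that X positions 1–2 evolve at roughly the autosomal
position-1–2 rate (the faster-X excess concentrated at synonymous
sites, i.e. fast substitution under strong purifying selection).

Gene trees come from a mixture of planted topologies (the species tree
plus alternatives separated by a configurable number of NNI moves, 14 in
the grove preset so the clusters are well separated) with per-locus
Poisson NNI noise. Contaminants are planted consistently in sequence
(donor copy with 0.2% mutations) *and* gene tree (recipient regrafted as
the donor's sister), since tree estimation is outside the package's
scope and QC operates on supplied gene trees; donor–recipient pairs are
drawn among distant taxa (patristic ≥ 1.8 time units), the domain the
concatenation-distance gate is designed to flag. Long-branch paralogs
stretch a terminal to 100× the mean edge before simulation. Missing
data are whole-taxon absences (5% per locus), boosted by +15% for male
samples at X loci. Coverage is negative-binomial around mean 100 with
size 200 (≈ 12% CV), reflecting that per-locus *mean* depth averages
over hundreds of positions and is far less dispersed than per-base
counts; male X cells have half the mean.

Not emulated: coalescent ILS (groves are a topology mixture, which is
what the clustering stage can detect), read-level artifacts, alignment
error, amino-acid data, and within-locus trimming. Passing tests
therefore demonstrate that the *analysis chain* recovers planted
structure of these kinds; they do not validate homology inference or
alignment upstream of it.

## Problem sizes used in tests and the acceptance script

The operating-characteristic checks run at sizes chosen to exercise the
statistics without waste: QC recall on 200 + 20 loci of 300 bp at 60
taxa; linkage classification on 900 + 100 loci with 5 + 5 sexed samples
and the type-I sweep over 200 null seeds; per-base signal on 50 loci of
500 bp at 8 taxa; grove recovery on 120 loci over three planted
topologies; and the NT12 regime change on the full `faster_x_demo`
preset over 10 seeds, with the complete X bin (15 loci) and a seeded
30-locus autosomal subsample per seed (medians over a random subsample
estimate the bin median without bias). The acceptance script repeats
the same computations with 5 seeds for the NT12 block.

## Known limitations

* The NNI-based Δ lnL considers only the two rearrangements of the focal
  edge, not a wider topology neighbourhood.
* The GTR distance estimator ignores among-site rate variation.
* k-means groves assume roughly isotropic clusters in PCoA space; the
  number of groves is an input, not an inference.
* With ≲ 50 edges the 50× long-branch rule cannot fire at all (see
  above) — a property of the published rule, preserved deliberately.
* The coverage model has no mappability or GC structure; only a sex-by-
  linkage mean effect with overdispersion.
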