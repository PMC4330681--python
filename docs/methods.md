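# Methods

This note documents the statistical procedures implemented in `traitniche`,
the modelling choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Distances

For each trait or ecological indicator the package builds two pairwise
matrices over species: the **absolute** distance |v_i − v_j| (symmetric,
non-negative) and the **hierarchical** distance v_i − v_j (anti-symmetric).
The absolute matrix asks *how different* two species are; the hierarchical
matrix additionally keeps *which* species sits higher on the gradient, which
is what lets a Mantel correlation detect directional trait–indicator
coupling. Elementwise, the absolute matrix is exactly |hierarchical|.

Indicator variables are used on their native printed scales (ordinal 0–9
Ellenberg scores; a 0–10 phosphorus-requirement score) without
normalisation: distances are only ever computed within one variable, so
rescaling would change nothing but units.

Missing values propagate: any pair involving a species with an NA value is
NA, placed symmetrically. NA handling is **pairwise-complete at
vectorization time** by default — each trait × indicator test uses every
pair for which both values exist — rather than dropping a species from the
whole analysis. A `listwise` policy (drop species with any NA indicator up
front) is available for sensitivity analysis. At least 3 usable species
(3 unordered pairs) are required, below which the statistic is refused.

## Mantel tests

The Mantel statistic r is the Pearson correlation of two matrices' aligned
pair vectors. Symmetric pairs vectorize over the upper triangle;
anti-symmetric matrices are **forced** to vectorize over all off-diagonal
cells. The reason is invariance: the upper triangle of an anti-symmetric
matrix changes sign pattern under species reordering, whereas the full
off-diagonal vector always contains +d and −d for each pair, has exact zero
mean, and gives a statistic invariant under joint relabelling.

The null distribution is generated by uniform random species relabellings
applied to the rows *and* columns of one matrix (permuting one side is
equivalent in distribution to permuting the other). NA masking is re-applied
per permutation. The p-value uses the add-one rule
p = (1 + #{r_perm at least as extreme}) / (n_perm + 1), so p ≥ 1/(n_perm+1)
and is never zero; ties are counted with a 1e−12 tolerance. Degenerate
permutations (constant pair vector after re-masking) are excluded from the
denominator; if all permutations degenerate the test errors rather than
reporting a number. Default n_perm is 999. For n ≤ 8 species
`mantel_exact` enumerates all n! relabellings and returns the exact
permutation p (a multiple of 1/n!).

Tail conventions follow the two hypotheses the workflow tests: absolute
distances against phylogenetic or indicator distances default to one-sided
*greater* (distant species should be **more** dissimilar if the variables
are coupled), hierarchical-vs-hierarchical tests default to *two-sided*
(the trait may increase or decrease along the gradient). Both are
overridable. No multiple-testing correction is applied by default (each
cell is reported at raw α = 0.05 with stars at 0.05/0.01/0.001); a Holm
step-down adjustment over each grid is available behind a flag.

The permutation engine is vectorised (all permutations' pair vectors are
gathered in one indexing operation), which is why a 1000-dataset × 999
permutation calibration takes seconds.

## Phylogeny

Pairwise sequence distances use either the p-distance (default — fewest
assumptions) or Kimura's two-parameter distance
d = −½ ln((1 − 2P − Q)·sqrt(1 − 2Q)) with P and Q the transition and
transversion proportions; columns with a gap or N in either sequence of a
pair are deleted pairwise. K2P is refused (with a pointer to the
p-distance) when its logarithm is undefined.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion Q(i,j) = (r−2)·d(i,j) − R_i − R_j. Two determinism/robustness
choices: ties in the Q minimisation are broken toward the lowest
(row, column) index pair, and negative branch-length estimates are clamped
to zero with the deficit logged. For additive inputs no clamping occurs and
the patristic distances of the output tree reproduce the input matrix to
float precision; this round-trip (plus exact topology recovery on random
trees) is the package's main correctness check for the implementation.

Bootstrap supports resample alignment columns with replacement; support is
the percentage of replicate NJ trees containing each internal split of the
point-estimate tree (splits compared as unrooted bipartitions). Replicates
in which some pair loses all comparable sites are dropped and logged.

Patristic distances (path sums over branch lengths) are delegated to
dendropy's phylogenetic distance matrix; a brute-force path-sum oracle and
a four-point-condition check over all quartets guard it in the tests.

## Phylogenetic signal (eigenvector regression)

The phylogenetic distance matrix is embedded by classical principal
coordinates analysis: Gower double-centering B = −½·J·D²·J followed by
eigendecomposition. Eigenvectors are kept unit-norm; axes with negative
eigenvalues (non-Euclidean inputs) are recorded but never selectable.
Axis retention defaults to the sequential broken-stick rule — keep leading
axes while their share of the positive-eigenvalue total exceeds the
broken-stick expectation b_k = (1/n)·Σ_{i≥k} 1/i, stopping at the first
failure — with a `first-k` alternative. If the rule retains nothing (e.g.
perfectly symmetric trees), the analysis falls back to the first axis and
says so in the run log.

Each trait is then regressed (OLS, with intercept) on the retained axes
over its non-NA species — the basis rows are subset, not recomputed — and
the overall regression F with (k, n − k − 1) degrees of freedom is referred
to the classical F distribution. A perfect fit reports F = +inf with p = 0;
a constant trait yields a flagged result with no signal claim. Because the
axes are fixed by the tree and the trait enters only as the response, the
test is exactly calibrated for white-noise traits — the acceptance suite
verifies the 5% nominal level empirically.

## Trait calculators

All calculators take measured units (cm², g, mm, m, cm³) and return the
conventional reporting units. Definitions with a genuine choice:

* **Taproot tissue density** is mass/volume (g·cm⁻³) — the density
  convention implied by its reported units.
* **Nodule investment** is nodule dry mass per unit root length (g·m⁻¹).
* **Fine-root tissue density** is reported in mg·cm⁻³ (values ~50–200).
* **Specific root area** has no universal formula; it is computed as
  cylinder lateral surface per dry mass, Σ(π·d_class·L_class)/mass, in
  dm²·g⁻¹. This makes SRA = 0.1·π·D·SRL an arithmetic identity.
* **depth95** fits an OLS line (with intercept) to the five points
  (segment lower boundary, cumulative fine-root length including that
  segment) and solves for 0.95 × total length. It is scale-invariant and
  undefined for empty or exactly flat profiles. Using all five cumulative
  points (rather than interior ones) is a documented choice.
* **Root length density** converts fine-root mass to length via mass × SRL
  (the dimensionally consistent reading), adds taproot length, and divides
  by pot volume.
* Trait summaries report min / mean / max / CV with the sample (n−1)
  standard deviation.

## Synthetic data

The generator emulates the motivating study design: 13 species scored on 6
indicators and 25 traits. Defaults in `SimulationConfig`: a Yule tree with
unit birth rate (branch lengths in expected-splits time units); Brownian
traits with unit variance per unit time (white-noise alternative for the
no-signal null); indicators = slope × trait + N(0, noise_sd) with slope 1
and noise_sd 0.75 — chosen from the closed form so that the population
correlation between hierarchical trait and indicator distances,
slope/sqrt(slope² + noise_sd²), equals 0.8 for a unit-variance trait;
missing-at-random cell fraction 0.1 (the packaged indicator table has
10/78 NA cells). A single integer seed drives a hierarchical stream (tree,
traits, indicators, missingness) so stages can be re-run independently.
Indicator values stay continuous rather than being rounded to ordinal
classes, preserving the planted correlation for power analyses.

`generate_trait_targets` draws physically consistent trait tables:
independent traits uniform within realistic field ranges, and the
arithmetically tied ones (specific root area, root-system biomass, taproot
percentage, root:shoot ratio, total biomass) derived, with mycorrhization
rates drawn as integer counts out of 300 intersects.
`generate_measurement_records` then constructs leaf, root-sample,
depth-profile and intersect-count records that invert through the trait
calculators to the targets at 1e−9 relative precision — the depth profile
uses a (u, u, u, u, T) cumulative pattern whose OLS fit hits any requested
depth95 below 135 cm, and the diameter-class pair is solved from the mean
diameter and very-fine fraction.

What the generator does **not** emulate: ordinal discreteness and bounded
ranges of real indicator scores, non-random missingness, measurement error
correlated across traits, non-Brownian trait evolution
(Ornstein–Uhlenbeck, rate shifts), and alignment-level realism (bootstrap
inputs are arbitrary site patterns). Passing tests therefore demonstrate
statistical correctness and calibration of the machinery, not that any
particular empirical dataset will show these effects.

## Problem sizes and numerical choices

The packaged checks use: 1000 datasets × 999 permutations at 10 species for
type-I calibration; 500 replicates at 13 species for planted-effect power;
100 random trees of 5–20 taxa for NJ recovery; 500 replicates per trait
model for the signal contrast; 100 random target tables for trait
round-trips. Eigenvalues are considered positive above 1e−10 of the
spectral scale; Mantel tie counting uses 1e−12; variance guards use 1e−30;
Pearson r is clamped to [−1, 1] against rounding. All Monte-Carlo draws go
through numpy Generators seeded explicitly; report CSVs are written with a
fixed float format so identical runs are byte-identical.

## Known limitations

* NJ is the only tree-inference method (no likelihood/Bayesian inference);
  the bootstrap annotates but does not collapse low-support edges.
* The eigenvector-regression signal test conditions on a fixed axis
  selection; model-selection uncertainty in the number of axes is not
  propagated.
* Mantel tests have known low power against some structured alternatives
  and the grid is reported without multiplicity correction by default.
* `mantel_exact` is limited to 8 species (n! enumeration).
* Hierarchical and absolute tests on the same pair of variables are not
  independent; the package reports both and leaves the synthesis to the
  analyst.
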