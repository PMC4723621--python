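# Methods

`metabofuse` implements a multi-platform metabolomics workflow of the kind
used to compare rice grain varieties across six analytical platforms:
headspace SPME–GC–MS volatiles, ¹H-NMR, direct-infusion ESI-MS in negative
and positive mode, GC–TOF–MS primary metabolites, and ICP-MS element
panels. The statistical core is a double cross-validated PLS-DA with a
permutation test on the misclassification count and rank-product
summarization of the per-model regression coefficients.

## Platform preprocessing

Each platform block is reduced from raw-ish instrument output by the rules
a practitioner would apply before fusion:

- **GC–MS mass signals.** Entries with signal-to-noise below 3 are replaced
  by a uniform draw in [2.4, 3.0) times the signal's noise estimate
  ("below" is strict: s/n = 3.0 passes through). Replacement draws come
  from a single seeded generator consuming one draw per table entry in
  signal-major order, so results do not depend on iteration details.
  Signals detected (s/n ≥ 3) in six or fewer samples are then discarded.
  *Detection* is evaluated before randomization: randomized sub-noise
  values are placeholders, not detections. The randomize-then-discard
  order follows the order in which the rules are stated for the workflow.
- **¹H-NMR.** Spectra are integrated into half-open 0.01-ppm buckets
  (left-closed; the bucket count is ⌈(stop−start)/width⌉) and scaled so
  the TSP-d4 reference region (δ 0.05 to −0.05) sums to 1. Bucketing
  conserves total intensity exactly because every axis point falls in
  exactly one bucket.
- **DI-MS.** Spectra are integrated into unit-m/z buckets over the 50–1000
  acquisition range and scaled to total spectrum intensity. Buckets that
  are zero in every sample are dropped afterwards; this is how a nominal
  950-bucket grid reduces to the few hundred informative mass signals a
  real study reports. Both normalizations are scale-invariant:
  f(c·x) = f(x) for c > 0.
- **ICP-MS.** The limit of detection per element is 3 × the sample SD of
  at least 7 blank replicates (fewer blanks is an error). Only data
  strictly above the LOD are usable; an element with *any* sub-LOD sample
  is dropped entirely so the fused matrix contains no missing values —
  PCA and PLS as implemented assume complete data, and imputation would
  introduce an uncited method. Measured certified-reference means must
  deviate strictly less than ±10 % from the certified values (a deviation
  of exactly 10 % fails).

## Fusion

Blocks are restricted to their common samples (canonical order = first
block's order), every variable is autoscaled — mean 0, unit sample SD with
the n−1 denominator, the chemometrics convention — and the blocks are
concatenated column-wise with per-column platform provenance. Autoscaling
gives every variable equal weight regardless of platform intensity scale.
Zero-variance columns are removed (their autoscaling is undefined and they
carry no information); with the six study-shaped blocks none arise and the
fused matrix is 44 × 1709.

Full-matrix autoscaling serves the unsupervised analyses only. Inside any
cross-validation loop, scaling parameters are recomputed on the training
fold and applied to the held-out sample, so the held-out sample never
influences the model. In that supervised context, training-fold columns
with zero variance are kept but assigned SD 1 (they center to all-zero and
carry no weight) rather than dropped — the rank-product summary requires
all n cross-validation models to share one variable set.

## PCA and the number of significant components

PCA is SVD-based; explained-variance fractions are σ²ₖ/Σσ² over the full
spectrum, and loading signs are fixed so each loading's largest-magnitude
entry is positive (deterministic across linear-algebra backends). The
number of *significant* components is selected by element-wise 7-fold
cross-validation: entries of the current residual matrix are randomly
partitioned into folds; each fold is masked and reconstructed by a rank-1
EM fit (impute-with-current-estimate / leading-SVD iterations); a
component is accepted while Q² = 1 − PRESS/RSS exceeds 0.05. The exact
rule used by commercial chemometrics packages is proprietary, so both the
fold count and the Q² limit are configurable; the defaults are the
standard published recipe. Testing stops at the first non-significant
component.

## Hierarchical clustering

Agglomeration uses Euclidean distance with Ward's linkage in its "Ward.D2"
sense — squared distances in the objective, merge heights reported on the
distance scale — delegated to scipy's nearest-neighbor-chain
implementation. Exact-tie merge order follows that implementation; with
continuous data ties have probability zero. Dendrograms export to Newick
with ultrametric branch lengths (a node merged at height h sits at depth
h/2), and the first cluster break is read off the root's two subtrees.

## PLS-DA

Class labels are coded as a 0/1 indicator matrix (one column per class,
one 1 per row). The model is NIPALS PLS2: components maximize X–Y
covariance; X is deflated after each component, Y is not; the inner
iteration runs to a relative tolerance of 1e-12 or 500 iterations.
Regression coefficients use the closed form B = W(PᵀW)⁻¹Qᵀ, which equals
the sequential deflation prediction (asserted to 1e-8 in tests), and at
full rank equals the least-squares solution. Prediction scales a raw
sample with the training parameters, applies B and adds back the training
Y-means. Class assignment is the argmax of the predicted indicators with
ties to the earliest class in the declared order. PLS2 (one model, one
coefficient column per class) is used rather than per-class PLS1 so that
multi-group comparisons yield one coefficient vector per class from a
single model.

## Double cross-validation, permutation test, rank products

The double CV is two nested leave-one-out loops. The outer loop sets one
sample aside; the inner loop, on the remaining n−1 samples, selects the
latent-variable count in 1..A_max by leave-one-out misclassification count
(ties go to fewer components — parsimony); the model is refitted with the
selected count and classifies the outer held-out sample. Every fold
rescales on its own training rows. This yields n models, n honest
predictions, and the misclassification count M.

A_max defaults to min(n_train − 2, p, 10); the simulation studies shipped
with the package use A_max = 5, a realistic ceiling when inner training
sets have ~18 samples. Significance of M comes from a permutation test:
class labels are shuffled (class sizes preserved) and the *entire* double
CV, inner selection included, is re-run per permutation;
p = (1 + #{null M ≤ observed M}) / (1 + n_permutations) (the add-one form
avoids p = 0). The default is 1000 permutations for analyses and 99 in
tests and simulation studies.

Variable importance: within each of the n models, variables are ranked by
descending |B| per class column (rank 1 = largest; ties receive average
ranks, which makes the summary invariant to variable order). The n ranks
are multiplied into a rank product, computed and stored as a sum of
log-ranks — exactly monotone in the product and immune to overflow even at
44 models × 1709 variables — alongside the geometric-mean rank
exp(mean log rank) ∈ [1, p]. Low rank products mark consistently important
variables. The report table lists the top-k variables with per-class
raw-scale means, SDs and a higher/lower flag. For two-class runs the two
coefficient columns are redundant and column 1 is reported.

Two behaviors of this design are worth knowing:

- **Chance level under permutation is slightly above 50 %.** With balanced
  classes, leaving one sample out makes its class the training minority,
  and the Y-mean intercept tilts predictions against it; permuted-label
  misclassification rates therefore center near 0.54–0.55 rather than
  0.50 for n = 20. This majority-vote anti-bias is a known property of
  leave-one-out under permutation and is why chance-level checks here are
  made at single-run resolution, where the binomial 99 % band is wide
  enough to contain it.
- **The permutation p is conservative.** M is a small integer with heavy
  ties, so P(p ≤ 0.05) under the null falls below 0.05 (measured ≈ 0.03–
  0.06 at n = 20, 99 permutations) — the usual discreteness effect.

## Synthetic data generator

The generator emulates the study design: 44 samples in two balanced
classes (the basmati/jasmine contrast) and six platform blocks of 518, 95,
634, 367, 82 and 13 variables — 1709 after fusion. Log-intensities are
Gaussian with per-variable baselines drawn in log[1e3, 1e5], within-class
SD `noise_sd` = 0.3 (≈30 % CV, typical for profiling platforms), and
intensities are exponentiated, so all values are positive (required by the
total-intensity and reference-region normalizations) and autoscaling
removes the arbitrary baselines. Discriminating variables (default ≈2 %
per platform) receive class-dependent log-mean shifts spanning
`effect_size` within-class SDs between the extreme classes, with random
sign per variable. Class structure is mean shifts only by default — the
simplest structure the PLS-DA/rank-product machinery must detect; an
optional `block_correlation` knob adds a shared per-sample factor per
platform (equicorrelated noise, marginal SDs unchanged) to emulate the
strong covariance of real spectral blocks, as used in the demonstration
scripts. The generator also produces raw-ish precursors (mass-signal
tables with noise estimates, ppm-axis spectra with a TSP-like reference
peak, m/z–intensity pairs, element panels with blank replicates) to
exercise every preprocessing rule, and a ground-truth sidecar naming the
discriminating variables.

What the generator does *not* emulate: chromatographic peak shapes,
retention-time drift, isotope patterns, metabolite-level correlation
beyond the single shared factor, heteroscedastic noise floors, or
within-variety replicate structure (replication is configurable but
defaults to independent samples). Passing tests therefore demonstrate the
statistical machinery on clean positive intensity data with known signal,
not instrument-level robustness.

## Numerical and design choices

- Sample SD (ddof = 1) everywhere, matching chemometrics convention.
- NIPALS tolerance 1e-12 / 500 iterations; for indicator Y the inner
  iteration converges in a handful of steps.
- Rank deficiency: if X is exhausted before the requested component count,
  the model truncates with a warning; the double-CV caps
  A_max ≤ min(n_train − 2, p) by construction.
- Degenerate inputs error early with named coordinates: non-positive
  noise estimates, sub-minimum blank counts, zero reference-region sums,
  singleton classes in the outer CV, unknown labels.
- Data files (blocks, fused matrix) print floats at 17 significant digits
  for exact round trips; result tables print 12 significant digits for
  byte-stable reruns.
- The compiled (numba) kernels implement column scaling, NIPALS, inner
  selection and the double CV; the Python API wraps these same kernels, so
  there is one implementation of the estimator.

## Problem sizes in the shipped studies

The simulation studies that accompany the package use n = 20 (10 per
class): p = 200 with 5 discriminators at effect 3 for recovery, p = 100
at effect 0 with 200 repetitions × 99 permutations for null calibration,
and p = 60 with half the variables at effect 5 for dendrogram recovery —
the latter because a Euclidean first split can only track the class
partition when the class contrast contributes a substantial share of
total variance. The full 44 × 1709 shape is exercised for fusion, PCA and
the end-to-end pipeline.

## Known limitations

- With few informative variables among many autoscaled noise variables,
  PLS-DA's covariance-based weights dilute the signal: at 5/200
  discriminators and n = 20, the double CV misclassifies a few samples
  even at very large effect sizes, although the rank product still
  recovers the discriminators and the permutation test detects the
  structure. Variable selection (not part of this workflow) would be
  needed for error-free classification there.
- The element-wise PCA cross-validation is O(folds × components × EM
  iterations × SVD); on 44 × 1709 it takes seconds per component, which is
  why the demonstration caps the tested components.
- Multi-class comparisons report per-class rank products; no multi-block
  (hierarchical) PLS or block-weighted fusion variants are implemented.
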