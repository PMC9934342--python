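# Methods

`cilgibbs` analyses the spatial arrangement of tumour cells in histology
regions through the lens of contact inhibition of locomotion (CIL).
Cells that maintain homotypic CIL keep a characteristic distance from
their neighbours; a tissue whose cell divisions and deaths respect such
a minimum-distance constraint is a spatial birth-and-death process whose
equilibrium is a Gibbs hard-core point process.  The package quantifies
how far each patient's cell pattern is from that inhibited equilibrium,
stratifies a cohort on the resulting metric, relates the stratification
to survival, and contrasts gene expression between the inferred
subgroups.

## Models and statistics

### Spatial birth-and-death chain and hard-core equilibrium

The simulator (`synthetic.gen_hardcore_pattern`) implements the jump
chain of the process in which divisions arrive at rate `m` per unit
area (uniform location) and each cell dies at rate `d`; a division
succeeds only if the daughter lies at least `h` from every existing
cell.  Constant rates are used: the equilibrium intensity is then
`beta = m/d`, and with `h = 0` the equilibrium is Poisson(`beta`).
With `h > 0` the chain converges to the Gibbs hard-core process with
intensity `beta` and hard core `h`; the tests verify the hard-core
constraint exactly and the equilibrium intensity and stationarity
empirically (drift between the third and fourth quarter of the count
trajectory, averaged over independent chains, is compatible with zero).
The default run length is 10x the expected equilibrium count in
accepted events (floor 1000), after which count trajectories show no
drift at the default study conditions.  The state after `n` events
follows the jump-chain law, whose stationary mean exceeds the
continuous-time mean by about half a cell; this bias is negligible at
the pattern sizes used and is covered by the tolerance of the
equilibrium test.

### K and L functions

`spatial.estimate_K` implements the standard estimator
`K(r) = |W| / (n(n-1)) * sum w_ij 1[d_ij <= r]` with isotropic
(Ripley), translation, border (reduced-sample) or no edge correction.
The isotropic weights use the closed-form circle-window intersection
for rectangles, valid for `r` up to half the shorter side; the default
grid stops at a quarter of the shorter side.  `L = sqrt(K/pi)` equals
`r` under complete spatial randomness; `L < r` signals inhibition,
`L > r` clustering.  The cumulative estimators are monotone by
construction; the border estimator is left as defined (it may dip where
the eroded point set changes).

The per-pattern coordinate `L_r` is the radius maximising `|L(r) - r|`
(argmax, ties to the smallest radius).  The argmax — a length — rather
than the maximal deviation is used because it is compared with, and
averaged against, the fitted interaction radius below; the deviation
itself is also reported.

### Geyer saturation model

The Geyer saturation process has density proportional to
`beta^n * gamma^U(x)` with `U(x) = sum_i min(sat, t_i(x))`, where `t_i`
counts `r`-neighbours of point `i`; `gamma < 1` is inhibitory,
`gamma > 1` clustered, and `gamma -> 0` with `sat = 1` recovers the
hard-core process.  `GeyerModel.fit()` maximises the Berman-Turner
discretised log-pseudolikelihood: a stratified dummy grid (one point
per cell, counting weights summing exactly to the window area) turns
the pseudolikelihood into a weighted Poisson regression in
`(log beta, log gamma)`, solved by damped Newton iteration (tolerance
1e-8, at most 100 iterations).  `log gamma` is constrained to
[-20, 20]: a pattern with no close pairs separates the regression
(the maximiser is at -infinity), and the boundary value represents the
hard-core limit.

Numerical choices that matter:

- **Dummy density** defaults to 16x the data intensity (floor 32x32
  grid).  The counting-weight quadrature error scales with cell size;
  at 4x the discretisation bias of `log gamma` on CSR patterns is of
  the same order as its sampling error, at 16x it is well below it
  (doubling the density further moves estimates by < 0.02).
- **Irregular parameters** `(r, sat)` are profiled over a grid:
  `sat` in {1, 2, 3} and 16 radii at the 5th-80th percentiles of the
  observed nearest-neighbour distances.  The upper cap matters:
  interaction radii are of nearest-neighbour order, and at radii beyond
  the upper NN quantiles nearly every point is saturated, the
  interaction covariate is almost constant, and the coefficient is so
  weakly identified that profile selection there is driven by noise
  (occasionally producing extreme fitted radii).  Explicit grids can
  always be supplied.
- **Border correction**: the pseudolikelihood is summed over
  quadrature points at least `max(r_candidates)` from the boundary, the
  same subset for every grid point, so profile values are comparable
  across `(r, sat)`.
- **Profile-selection bias**: on CSR data, profiling over 48 grid
  points selects the most extreme noise direction, inflating
  `|log gamma|` even though the estimator at any fixed `(r, sat)` is
  unbiased.  No-interaction calibration is therefore assessed at a
  fixed interaction scale, matching how the model is used with a
  pre-chosen radius.

The simulator (`simulate_geyer`) is a birth-death Metropolis-Hastings
chain with the Papangelou conditional intensity
`lambda(u; x) = beta * gamma^Delta(u; x)`; the default run length is
`n_sweeps = 400` times the expected count in proposals.

### The inhibition metric and cohort stratification

Each patient contributes `M(r) = (L_r, G_r)` with `G_r` the fitted
Geyer interaction radius.  Both optima are computed over the same
radius range (the Geyer candidate range): the coordinates are compared,
z-scored jointly and averaged downstream, so letting one optimum roam
over a much larger range than the other would make the pair
incommensurable — with a common range, inhibited patients show
`L_r ~ G_r ~ h` while clustered patients land at small radii with
`gamma > 1`.

Coordinates are z-scored across the cohort (sample SD, n-1).  The
number of groups is chosen by majority vote of ten cluster-validity
indices (silhouette, Calinski-Harabasz, Davies-Bouldin, Dunn, gap
statistic with the one-SE rule, C-index, McClain-Rao, Ratkowsky-Lance,
point-biserial, Ball-Hall), each implemented from its published formula
and unit-tested against hand computations; ties go to the smaller k.
k-means (k-means++, 50 restarts, Lloyd to relative tolerance 1e-10)
splits the cohort.  Group naming has two rules.  On bare metric points
the cluster with the larger within-cluster variance (mean squared
deviation from its centroid) is named **Invasion** and the tighter one
**Gibbs**, since convergence of the Gibbs model concentrates `L_r` and
`G_r` for inhibited patients; an exact tie is broken by centroid norm.
Downstream of the model fits, where each patient carries a fitted
interaction strength, the cluster with the smaller mean `log gamma` is
the Gibbs group: the fitted `gamma` is the direct evidence of
inhibition, and unlike the dispersion heuristic it does not flip when
the two clusters happen to be comparably dispersed.  The
incremental-centroid trajectory re-runs k-means on growing patient
prefixes, matching cluster identities between consecutive sizes by
nearest-centroid continuity.

### Survival association

The mean inhibition metric `MIM = (z_L + z_G)/2` is computed on the
z-scored coordinates.  Within a group, the MIM sequence ordered by
increasing survival (ties by patient id; censored patients keep their
observed time) is Loess-smoothed (local linear, tricube weights over
index position) and compared with the same values under one seeded
random permutation.  Membership of each smoothed value in the band
`centroid MIM +/- 4 SD` — centred on the group's k-means centroid
collapsed to the MIM scale, with SD taken from the randomized smoothed
series — gives a 2x2 table (ordering x inside/outside) tested with a
two-sided Fisher exact test (own hypergeometric enumeration, verified
against exhaustive enumeration for all tables with margins up to 30).

The Loess span defaults to 0.3.  The span controls both smoothness and
the autocorrelation of the smoothed series, and with it the calibration
of the band test: at wide spans the smooth leaves the band in long
correlated runs and the Fisher test rejects far too often under the
null, while at very narrow spans the band (scaled by the rougher
randomized smooth) swallows everything.  Span 0.3 makes the null
rejection rate approximately nominal (about 4-5% at the 5% level over
500 simulated null cohorts of 100 patients), which we verified by
simulation; the figure is recomputed by the acceptance script.

The establishment point is the first index from which the
survival-ordered smooth stays inside the band for good; the survival
time at that index splits the group into LH-CIL (below) and H-CIL (at
or above), a partition with no unassigned patients.  Kaplan-Meier
curves and the two-group log-rank test come from lifelines; a group
with no observed events flags the test unreliable.

### Differential expression

Raw counts are normalised with TMM factors (30% log-ratio trim, 5%
abundance trim, inverse-variance weights, reference = sample with the
upper quartile closest to the mean; factors rescaled to geometric mean
one) — the implementation reproduces the reference R implementation to
1e-6 on a frozen fixture.  Each gene with total count >= 10 is fitted
with a negative-binomial GLM (log link, offset = log effective library
size) under the two-group and intercept-only models, vectorised across
genes by Fisher scoring on the group means; a per-gene statsmodels GLM
is the independent cross-check in the tests.  Gene-wise dispersions
maximise the Cox-Reid adjusted profile likelihood on a log-spaced grid
(the unadjusted profile is biased low because the group means are
estimated, which inflates the type-I error) and are shrunk in log space
toward a lowess mean-dispersion trend with prior weight 10 against the
residual degrees of freedom.  The group effect is tested by
likelihood-ratio chi-square (1 df) with Benjamini-Hochberg adjustment;
the study cutoffs are FDR < 0.001 and |log2FC| > 6, with positive
log2FC meaning higher expression in LH-CIL.

The signature table divides each gene's two group means by their
root-mean-square, applies `log2(x + 1)`, and keeps genes whose absolute
transformed difference exceeds 0.2 (the transformed scale is used for
the filter; the raw-mean direction determines the movement-direction
counts).

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, at study
conditions fixed once:

- **Patterns**: 300 um x 300 um windows ("a 300 um region" read as a
  300 x 300 um square crop); CSR at ~200 cells per window; hard-core
  phenotype at `beta` = 200 cells/window with `h = 12 um` (a glioma
  nucleus diameter); Thomas clusters with ~25 parents/window, 8
  offspring, 6 um spread.  Patients vary: per-patient hard core and
  intensity are jittered +/-15%, Thomas parameters +/-40%, reflecting
  between-tumour heterogeneity in cell size and packing (invasive
  tumours are the more variable group, which is also what the
  variance-based group naming encodes).
- **Images**: nuclei as 4-um disks in a haematoxylin-like purple on a
  pale eosin background with additive Gaussian pixel noise, plus the
  ground-truth centres.  Real slides add touching nuclei, stain
  gradients, and non-nuclear dark objects; none of these are rendered,
  so passing round trips show correctness of the segmentation chain,
  not robustness to real staining artefacts.  Touching nuclei are
  deliberately not split (no watershed), matching the k-means +
  centre-of-mass protocol; dense real tissue is therefore undercounted.
- **Cohorts**: exponential survival at scale 600 days for inhibited
  and 150 days for clustered patients, ~10% uniform right-censoring.
  Real survival is not exponential and censoring is not uniform; the
  cohort tests demonstrate recovery of a planted two-phenotype
  structure, not clinical realism.
- **Counts**: NB counts (dispersion 0.1) with log-normal baselines,
  library sizes x[0.5, 2], and a planted DE fraction shifted in the
  H-CIL group, with the planted list recorded as ground truth.

All generators are bit-reproducible for a fixed seed.

## Degenerate inputs and edge cases

- Patterns with fewer than 2 points cannot enter K estimation
  (explicit error); fewer than 10 (configurable) cannot be fitted, and
  such patients carry NaN metrics through the cohort stage.
- A hard core exceeding the window diagonal warns and yields at most
  one point.
- Single-colour images segment to an empty mask with a warning;
  centroids smaller than the area of a 2-um disk are filtered.
- A zero-variance metric coordinate, a zero-width band, and an
  all-zero count sample raise errors; an all-censored survival group
  flags the log-rank test unreliable instead of failing.
- The profile fit reports a boundary `log gamma` (+/-20) when the data
  separate; non-convergence at every grid point raises with the full
  profile attached.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
the sizes above: 100 CSR patterns for calibration, 20 replicates for
the hard-core, recovery, consistency and segmentation checks, a
411-patient cohort (266 inhibited, 145 clustered) for stratification,
500 null cohorts for band-test calibration, and 20x500 null genes plus
a 2000-gene planted matrix for the expression stage.  These sizes give
each Monte-Carlo check a sampling error comfortably below its
acceptance margin.

## Known limitations

- Pseudolikelihood, not likelihood: interaction estimates carry the
  usual MPLE small-sample bias; no MCMC-MLE refinement is provided.
- The profiled saturation grid {1, 2, 3} is a pragmatic default, and
  `G_r` is defined as the profiled Geyer interaction radius; an
  explicit hard-core component is not fitted separately (the minimum
  nearest-neighbour distance is reported alongside).
- The Fisher band test treats smoothed points as exchangeable units;
  its calibration holds at the defaults (span 0.3, 4-SD band, one
  permutation, groups of ~100) and should be re-checked by simulation
  if those are changed materially.
- The ten-index battery preserves majority-vote behaviour but is not
  an index-for-index reimplementation of the full 30-index R battery.
- Exact parity with the reference R differential-expression stack is
  not claimed: TMM matches it numerically, but dispersion shrinkage
  follows the empirical-Bayes construction described above rather than
  mirroring that package's estimator internals.
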