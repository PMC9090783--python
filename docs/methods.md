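# Methods

This note records the models implemented by `brcalike`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Copy-number pipeline

**Coordinates and counting.** All genomic intervals are 0-based, half-open
(BED convention). A read is assigned to the unique bin whose interval
contains its 5′ start; reads on non-autosomes or outside the grid are
dropped and tallied, malformed records are skipped and counted, and
`assigned + dropped + skipped = input` always holds. The autosome set is
names 1–22, accepted with or without a `chr` prefix and normalized
internally.

**Bin filtering.** A bin is included iff it is not blacklisted and its
reference mappability is at least 0.2. The threshold is inclusive: the
exclusion rule is "below 0.2", so a bin at exactly 0.2 is kept. Lowering
the threshold can only add bins (monotonicity, covered by a test).

**GC correction.** The loess fit of counts on GC uses tricube distance
weights and local quadratics, with span 0.3 by default (the span is a free
parameter; 0.3 is a conventional middle ground between bias and variance
for ~5000-bin genomes and is configurable). Only included bins with
mappability strictly above 0.8 train the fit. Two bisquare robustness
iterations follow the initial fit so that bins carrying genuine copy-number
signal do not drag the bias estimate; because the bisquare weights depend
only on residuals relative to their median absolute value, the fitted curve
remains exactly proportional to the counts, preserving depth invariance.
The curve is evaluated on a ≤200-point quantile grid of the training GC
values and interpolated linearly; GC values outside the fitted range use
the nearest fitted value. Each included bin's count is divided by the
fitted value at its GC and multiplied by the mean fitted level, so
corrected counts keep the scale of the input.

**Reference scaling.** "Center of GC-corrected counts per mappability
density" is read as density-weighted group centers: included bins are
grouped into 20 equal-width mappability intervals on [0.2, 1]; each
non-empty interval contributes (median mappability, median corrected
count) weighted by its occupancy, and a weighted least-squares line through
the origin over these centers gives the slope. This is one defensible
reading of a terse description; the grouped-median construction makes the
slope robust to aberrant segments while the occupancy weights preserve the
"density" qualifier. The fit requires bins spanning at least three
mappability deciles and a strictly positive slope.

**Degenerate bins.** A bin whose corrected count is not positive is removed
from the inclusion mask rather than given an infinite or pseudo-count
ratio: pseudo-counts distort exactly the low-count bins where the signal is
weakest, while dropping the bin keeps every reported ratio finite without
inventing signal.

**Numerical properties.** Every stage is linear in the counts, so
multiplying raw counts by any c > 0 leaves the log2 profile unchanged to
~1e-15; the test suite asserts 1e-6.

## Shrunken-centroid classifier

Training follows the standard nearest-shrunken-centroid recipe: class
means, pooled within-class standard deviations s_k, fudge constant s0 set
to the median of the s_k, standardization factors m_j = sqrt(1/n_j − 1/n),
soft-thresholding of the standardized contrasts by Δ, and Δ chosen from a
grid (30 points from 0 to the largest observed contrast by default) by
stratified cross-validated accuracy, with ties resolved toward the larger —
more parsimonious — Δ. Class priors default to equal and are configurable;
nothing in the implemented problem fixes them otherwise.

Scoring uses the diagonal Gaussian discriminant and a numerically stable
softmax of −δ_j/2; the two class posteriors sum to 1 to 1e-9. The decision
threshold is 0.63 on the BRCA1-like posterior, and a score exactly at the
threshold is called BRCA1-like (the cutoff is "greater than or equal").
Because the two discriminants share their quadratic term, the score is
monotone along any line from one centroid to the other.

Profiles are mapped onto interval features as the mean log2 ratio of
included bins overlapping each feature. A feature with no included bins is
imputed with the overall centroid — the score-neutral direction — rather
than zero, which would masquerade as a confident "no aberration". A profile
leaving more than half the features empty is rejected as
quality-insufficient; cohort classification records such failures per
sample instead of raising.

## Concordance

The percentile of a cutoff is 100·(#scores strictly below)/n, and the
matched cutoff on the second score is the linearly interpolated empirical
quantile at that percentile; ties resolve to the high class. These
conventions make the marginal match exact to within 1/n on tie-free data
and self-concordance exactly 1 for any cutoff, including the boundary case
where the cutoff exceeds every score (the matched cut then falls just above
the maximum). Whether the original analysis interpolated or used nearest
ranks is unknowable from the description; discrepancies of at most one
sample are possible, which is why the marginal-match contract is stated as
within 1/n.

## Survival analysis

**Endpoints.** RFS time is the minimum of recurrence time, death time and
follow-up end, with an event iff recurrence or death occurred; OS counts
death only. An event time recorded after the end of follow-up is rejected
as inconsistent. Median follow-up is the first time the reverse
Kaplan–Meier curve (indicators flipped) reaches ≤ 0.5, with "not reached"
represented as infinity.

**Cox fitter.** Newton–Raphson on the log partial likelihood with
step-halving, converging when the gradient max-norm falls below 1e-8;
near the optimum a candidate step is accepted when it does not decrease the
log-likelihood by more than 1e-10·(1+|ll|), the float-rounding floor at
cohort scale. Efron's ties correction is the default (times are in years,
ties plausible); Breslow is available and is what the grid-search oracle in
the tests uses. Coefficient divergence beyond |β| = 30 is reported as
probable complete separation. Wald 95% intervals use exp(β ± 1.96·SE) and
two-sided α = 0.05 throughout.

**Interaction model.** The treatment×marker analysis fits
h(t|T,M) = h0_M(t)·exp(β₁T + β₃TM): the baseline hazard is stratified by
marker status and the design carries treatment and treatment×marker. With
a shared (unstratified) baseline, exp(β₁) only approximates the
marker-negative stratum HR (differences around 1e-2 at a few hundred
patients per cell); stratifying makes the partial likelihood factorize
across strata, so exp(β₁) and exp(β₁+β₃) equal the stratum-restricted fits
exactly, which is the contract the package promises and tests. The
marker's own prognostic hazard ratio, absorbed here by the stratified
baselines, comes from a separate unstratified fit. Adjustment is one
covariate at a time — never all at once — reflecting the small event counts
such trials have; categorical covariates are dummy-coded against the first
level in a fixed order.

**Proportionality.** Scaled Schoenfeld residuals (Efron-averaged risk-set
means within tie groups) are correlated with event time on the identity
scale, giving the usual per-term 1-df chi-square. Calibration (≈5%
rejection under proportional hazards) and power against a sign-flipping
effect are checked by simulation in the test suite.

## Synthetic-data generators

The generators produce every input of the chain with known ground truth.

* **Bin grids.** GC is a moving average (window 25 bins) of uniform noise
  rescaled to [0.3, 0.7] per chromosome — spatially autocorrelated like
  real GC without external tracks. Mappability comes from three strata
  (5% below 0.2, 70% above 0.8 by default, the rest in between) and 2% of
  bins are blacklisted, so the filtering rules have work to do.
* **Copy-number signal.** Fixed class-characteristic region shifts plus
  random segmental shifts (Poisson breakpoints per 100 Mb, Gaussian segment
  levels) plus per-bin Gaussian noise. The regions that distinguish the two
  classes are free simulation parameters, not claims about which loci
  characterize BRCA1-like tumours.
* **Counts.** Poisson with mean depth·2^log2·mappability·exp(quadratic in
  GC). Poisson rather than negative-binomial keeps the oracles closed-form
  and the pipeline under test makes no distributional assumption; an
  optional Gamma–Poisson overdispersion parameter is provided.
* **Cohorts.** Recurrence times are exponential within each arm×marker
  cell; death follows recurrence after an exponential delay (rate 0.5/yr),
  and everyone is administratively censored at the follow-up horizon.
  Defaults emulate the adjuvant-capecitabine TNBC trial setting: stratum
  treatment HRs 0.23 (marker-negative) and 0.66 (marker-positive), a
  prognostic marker HR of 0.74, a control-arm marker-negative hazard of
  0.059/yr (the value for which 10.7 years of follow-up yields the
  trial's control-cell event fraction of 15/32), censoring at 10.7 years,
  and covariate frequencies matching the trial's Table-1-style population.
  Deaths without prior recurrence are not modeled separately, so RFS is
  the endpoint whose hazards the configuration controls exactly; OS is a
  delayed transform of it.
* **Paired scores.** A Gaussian copula on ranks; the latent correlation is
  found by Brent root-finding so the marginal-matched dichotomization hits
  a target concordant fraction asymptotically. An exact-count constructor
  builds n pairs with a specified number of concordant calls and an equal
  split of disagreements, for reconstructing published 2×2 tables.

All randomness flows from one integer seed through named
`numpy.random.Generator` instances; no global RNG state is used.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: FFPE artefacts, wavy genomic baselines, replication
timing, subclonality and tumour-cell fraction, segment length distributions
of real breast cancers, informative (non-administrative) censoring, and
covariate-outcome confounding. Results on these simulations validate the
mechanics and the statistics of the chain, not clinical performance.

## Problem sizes

The standard scales used by the tests and the acceptance script: 5000-bin
genomes at mean depth 100 for pipeline properties; 200-feature, 40-per-class
cohorts for classifier recovery; 103 score pairs; cohorts of 2000 per
arm×marker cell (averaged over 5 replicates) for hazard-ratio recovery, 100
per cell × 200 replicates for null interaction-p calibration, and 300
patients × 200 replicates for Wald coverage. At 2000 per cell a single
cohort's marker-positive stratum HR has Monte-Carlo standard error ≈ 0.035,
so recovery is assessed on the 5-replicate mean.

## Known limitations

* The loess evaluator interpolates between ~200 grid points; exactness on
  polynomial inputs is to ~1e-5 relative, not machine precision.
* The feature-grid mapping averages bins uniformly within a feature; no
  within-feature weighting by bin width or mappability.
* The Schoenfeld test uses the identity time transform only.
* `fit_cox` rejects designs with a globally constant column but does not
  detect all rank deficiencies before the information matrix turns
  singular; such fits raise at the solve step.
* The exact-count paired-score constructor requires an even number of
  discordant pairs (they are split equally between directions).
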