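# Methods

## The analysis

`tracttraj` implements a longitudinal ecological analysis of neighborhood
context and health at the census-tract level.  Each tract carries a poverty
percentage and a White-population share at three decennial time points
(1990, 2000, 2010), a 2010 population density, 12 social determinants of
health (SDOH), and 14 modeled health prevalences (7 health risk / preventive
behaviors, 7 health status / outcomes).  The pipeline has four stages.

**1. Trajectory classification.**  Each composition value is cut into three
ordered levels.  Poverty uses the a-priori fixed bands (−, 5], (5, 20],
(20, −] percent; a group share uses empirical tertiles (or fixed bands, for
synthetic data whose generating bands are known).  The ordered level triple
is mapped to one of five trajectories — long-term low / moderate / high,
increasing, decreasing — or to an undefined sink.  Two total mappings of the
27 possible triples are provided:

* `monotone` (default): a non-constant triple must never step against its
  direction (3 constant / 7 increasing / 7 decreasing / 10 undefined);
* `endpoint`: direction read from first vs. last level only (3/9/9/6).

The published analysis names the five trajectories and reports 29 tracts
with "no discernible pattern" without enumerating the mapping; `monotone` is
our reading of a sustained direction, and `endpoint` is kept as a switch.
Tracts missing any year are excluded first (reason `missing_data`), then
undefined patterns (`undefined_pattern`); an ordered ledger records counts
and satisfies input = labeled + excluded at every stage.

**2. Linkage.**  Trajectory assignments for both variables are inner-joined
with the SDOH and health tables on the 11-digit tract identifier; tracts
missing from any source are ledgered (`not_in_sdoh`, `not_in_health`).
Population-density quartiles are computed on the final analytic set with
linear-interpolation percentiles (the package-wide convention, shared with
medians and tertiles); values at or below a cutpoint fall in the lower
quartile, so ties always share a quartile.  Q4 (highest density) is the
regression reference level.

**3. Association battery.**  For each exposure — poverty trajectories
(reference long-term low) and share trajectories (reference long-term
high) — and each of the 26 outcomes:

* a one-way fixed-effects ANOVA across trajectory groups;
* an OLS model of the outcome on 4 trajectory dummies + 3 density-quartile
  dummies, with classical standard errors and two-sided t tests.

Six right-skewed measures are log-transformed before modeling (natural log):
the two healthcare distances and median home value with offset 0, and
crowded housing, public assistance, and limited English proficiency with
offset 1 (these contain zeros).  The ANOVA uses the same transformed scale
as the regression so the screen and the adjusted model test the same
quantity.  Significance uses the fixed family-wise threshold p ≤ 0.001 (a
Bonferroni-style guard for the many tests), not α/m recomputed from the
test count.  Missing outcome values are dropped per model (complete case).
Empty or constant dummy columns (absent levels, degenerate density) are
dropped with a recorded warning rather than silently absorbed.

**4. Ancillary logistic model.**  A tract has a *negative poverty
trajectory* if it is long-term high or increasing in poverty.  The indicator
is regressed on the share-trajectory dummies (reference long-term high) by
maximum likelihood, with Wald 95% intervals on the odds-ratio scale.  It is
unadjusted for density by default (an `adjust_density` switch exists).
Perfect separation is flagged in the result instead of raising.

## The synthetic-data generator

The study's source tables (a commercial harmonized tract panel, a federal
SDOH compilation, modeled small-area health estimates) are not
redistributable, so the package ships a generator that reproduces the
statistical structure the analysis assumes.  Its defaults *are* the study
conditions: 5265 tracts, 69 planted missing-poverty tracts, 29 planted
non-classifiable patterns, 2961 health-covered tracts, and the published
trajectory shares as mixture probabilities (the printed shares sum to
100.1%; they are renormalized).

* **Latent classes.**  Each tract draws a poverty class from the five-class
  mixture and a share class through a comonotone-mixture copula: with
  probability *s* (co-occurrence strength) the share class reuses the
  poverty class's latent uniform, otherwise an independent one.  Classes are
  ordered by disadvantage (poverty) and advantage (share), so a shared
  uniform couples low-poverty histories with high-share ones.  The default
  *s* = 0.55 was derived from the two published cross-tabulation cells
  (62% of long-term-low-poverty tracts long-term-high White ⇒ s ≈ 0.53;
  71% of long-term-high-poverty tracts long-term-low White ⇒ s ≈ 0.57).
* **Band-consistent paths.**  Constant classes draw all three years
  uniformly inside one band; increasing/decreasing classes draw one of the
  seven band-monotone triples uniformly and then values within bands.  By
  construction, classification with the generating bands recovers the
  latent class for every tract, which the recovery tests exploit.  The HIGH
  poverty band is drawn on (20, 60] percent for realism.
* **Outcomes.**  Each outcome is intercept + trajectory effect +
  density-quartile effect + Gaussian noise on its modeling scale;
  log-registry outcomes are exponentiated afterwards, so the pipeline's log
  transform linearizes them exactly.  Default effects are the published
  poverty-model contrasts; the intercept is set so the mixture-weighted mean
  of the linear predictor equals the published statewide median (nudged
  inside the support by 0.5% of its width where the additive contrasts
  would push a reference cell outside).  Default noise is the residual SD
  implied by the published standard error of the long-term-moderate contrast
  (se / √(1/n_LTM + 1/n_LTL) at N = 2961), capped by bisection so the
  expected fraction of draws outside a bounded support stays below 0.01%.
* **Clipping guard.**  Bounded outcomes are clipped to their support only
  when the *expected* clipped fraction implied by the configuration is below
  0.1%; otherwise generation aborts, because silent truncation would bias
  parameter recovery.  The guard is evaluated analytically from the cell
  means and noise SD, not from one realization.
* **Density** is log-normal (median 1000, log-SD 1; persons per square
  mile), independent of class.  Quartiles are computed empirically
  downstream.  Health-table coverage keeps the densest classifiable tracts,
  emulating modeled estimates existing only for urbanized tracts.
* **Determinism.**  All draws flow from `numpy.random.default_rng` seeded
  with (seed, stream) pairs per stage; identical configurations are
  byte-identical, including CSV output (fixed `%.10g` float format, no
  timestamps in the run log).

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: spatial structure (no adjacency,
coordinates, or spatial autocorrelation), within-band distributional shape
(uniform, not the skewed empirical distributions), correlated errors across
outcomes (all 26 outcomes draw independent noise), measurement error in the
modeled health estimates, and any nonlinearity of the true
trajectory–outcome relationships.  Bounded percentage outcomes with large
published residual scales (e.g. renter occupancy) necessarily receive much
smaller noise than real data, because a linear-Gaussian emulation cannot
carry that spread inside [0, 100] under the clipping guard.

## Numerical conventions

* Percentiles (tertiles, density quartiles, medians) use linear
  interpolation throughout; a value equal to a cutpoint falls in the lower
  category.
* Band boundaries: LOW iff v ≤ edge1; MODERATE iff edge1 < v ≤ edge2 —
  matching the printed "0–5%, 5–20%, >20%" while keeping bands disjoint.
  With degenerate (all-equal) tertiles both cutpoints coincide and every
  tract is LOW by this rule.
* Tertile scope defaults to per-year distributions; a pooled variant is
  available.
* OLS is fitted by `statsmodels` and verified in the tests against a
  from-scratch normal-equations solve at 1e-10; the vectorized multi-outcome
  fitter used in calibration studies shares its algebra and is checked
  against single fits.
* Logistic Wald intervals use z = Φ⁻¹(0.975); on a collapsed 2×2 design the
  MLE odds ratio equals the contingency cross-product ratio, which the
  tests assert at 1e-8.

## Study sizes used in the checks

The calibration studies run at the sizes the contracts name: the exclusion
reproduction at 5265 tracts; type-I calibration over 20 000 null outcome
fits at n = 1000 (rejection rate of the four trajectory terms within three
binomial standard errors of 0.001); recovery of +2-point hypertension-style
contrasts over 500 replicates at n = 3000 (each coefficient within three
standard errors of 2 in ≥ 99% of replicates).  Unit tests use scaled-down
scenarios (hundreds to a few thousand tracts), chosen as the smallest sizes
at which the sampling tolerances are comfortably met.

## Known limitations

* The pipeline reports ecological (tract-level) associations only;
  individual-level inference is out of scope by design.
* The trajectory mapping for non-monotone patterns is a modeling choice the
  source analysis does not pin down; both provided rules are defensible.
* The fixed p ≤ 0.001 threshold is conservative and not adaptive to the
  actual number of tests run in a custom battery.
* No spatial modeling, multilevel structure, or mediation analysis.
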