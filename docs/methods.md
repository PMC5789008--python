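# Methods

## Overview

The package implements a population-level gene-by-environment analysis in
five stages: (1) aggregation of sample-level allele frequencies into one
weighted frequency per population per polymorphism; (2) construction of a
dopaminergic gene-system index from the first principal component of the
inter-locus correlation matrix; (3) a climatic-demand index from monthly
temperature extremes; (4) moderated regression of population trait means on
the index, demand and their product, with directional tests and robustness
machinery; (5) a synthetic-data generator that reproduces the statistical
structure the analysis assumes. Stages 1–4 are pure functions of their
input tables; stage 5 is the package's test bed and the source of every
fixture used by the test suite.

## Aggregation

A literature sample is one (population, polymorphism, frequency, N) record.
Within a population, records for the same polymorphism are combined by
sample-size weighting, `Σ n_i f_i / Σ n_i` — the fixed-effect pooled
estimate when each sample measures the same underlying frequency.
Frequencies are first oriented to a fixed canonical allele per polymorphism;
a record reporting the complementary allele enters as `1 − f`. Exact
duplicate sample ids for one (population, polymorphism) cell are an error:
the same study population must not be double counted. Resolving *near*
duplicates (the same cohort published twice under different ids) requires
bibliographic knowledge and is left to data curation, upstream of this
package.

The DAT1 VNTR is stored as the frequency of carrying at least one 9-repeat
allele — a carrier frequency, not an allele frequency. It occupies the same
[0, 1] column and is deliberately treated identically by every downstream
stage.

## Gene-system index

Correlations between loci are computed over pairwise-complete populations
(each pair needs ≥ 3 shared observations). Pairwise-complete matrices need
not be positive semidefinite, so before eigenanalysis the matrix is
repaired: eigenvalues are clipped at a floor of 1e-6, the matrix is
reconstructed and rescaled to a unit diagonal, and — because the rescale
can push an eigenvalue back below the floor — the clip-and-rescale step is
iterated to a fixed point. This makes the repair idempotent to machine
precision and is the conventional minimal correction for this failure mode;
an already-PSD matrix passes through untouched.

The first principal component's loadings are `eigenvector·√eigenvalue`.
Sign indeterminacy is resolved by an anchor convention: the DAT1 9R-carrier
loading must be positive, so a higher index always means higher inferred
dopaminergic function. Population scores are loading-weighted sums of
z-scored frequencies with the weights renormalised over each population's
available loci, `Σ λ_j z_pj / Σ |λ_j|`; populations with fewer than 5 of
the 9 loci are excluded with a warning. This scoring rule was chosen over
regression-method factor scores because it is monotone in every locus,
robust to missing cells, and reproducible without inverting an estimated
covariance matrix; the two coincide up to scale when the one-factor model
holds exactly. Scores are presented on a 0–100 scale anchored at the
observed minimum and maximum.

Reliability is summarised by the mean inter-item correlation r̄ (after
reflecting negatively loading items) and the standardised Cronbach alpha
`k·r̄/(1+(k−1)·r̄)`, both computed on the smoothed correlation matrix that
the PCA itself consumes. Agreement between the sample-level solution (each
literature sample as an observation) and the population-level solution is
measured per component by Tucker's congruence coefficient; since each
component is only identified up to sign, congruence is reported after
matching signs (equivalently, as |φ|).

## Climatic demand

Demand is `Σ |T − 22 °C|` over the coldest month's low and high and the
hottest month's low and high. 22 °C is the established reference optimum
for human thermal functioning; both colder and hotter extremes add demand.
No latitude adjustment is applied — unadjusted demands give the more
conservative estimate of climate effects. The reference temperature is a
parameter (`reference=22.0`) for sensitivity analyses.

## Moderated regression

All continuous predictors are mean-centred over the model's complete cases
before the product term is formed. The reduced model contains the main
effects (plus any covariates and continent dummies); the full model adds
`DA·CD`. The interaction increment is tested with
`ΔF = ΔR² / ((1−R²_full)/(n−p_full))` on (1, n−p_full) df, which equals the
squared t of the product term — an identity the test suite asserts. The R²
partition reported (main effects, interaction, full) is additive by
construction.

Directionality: the hypothesis fixes the interaction sign a priori
(positive for approach traits, negative for avoidance traits), so the focal
predictor and the product term get one-sided p-values — half the two-sided
p when the estimate matches the hypothesised sign, 1 minus that otherwise.
Other terms (intercept, moderator main effect, covariates, dummies) carry
two-sided p-values: no direction is hypothesised for them, and a one-sided
test without a direction is undefined.

Coefficients are reported on two scales: the raw centred scale of the input
variables, and a predictor-standardised scale (each predictor z-scored with
ddof = 1, the product formed from z-scores), obtained by exact analytic
rescaling of the same fit — `b·sd(x)`, `b·sd(z)`, `b·sd(x)·sd(z)`.

Simple slopes of DA are evaluated at ±1 SD of the centred moderator over
the model's complete cases: `slope(z0) = b1 + b3·z0` with
`SE² = var(b1) + z0²·var(b3) + 2·z0·cov(b1,b3)`, referred to the full
model's residual df. The SE is identical to refitting with the moderator
recentred at z0 and reading off the focal coefficient — the test suite
checks this identity.

The bootstrap resamples populations (the observation unit) with
replacement, refits the full model within each resample (recentring
inside the resample), and reports the percentile CI for the interaction and
the sign-based p `2·min(frac ≤ 0, frac ≥ 0)`. Resamples with a
rank-deficient design — e.g. a continent level that vanished — are redrawn,
up to ten times the requested number. Default B = 1000, deterministic under
a seed.

Multivariate outliers are screened by squared Mahalanobis distance from the
centroid referred to χ²(p), with Bonferroni flagging at 0.05; Bonferroni is
also the multiple-testing adjustment exposed (`min(1, m·p)`). Both
procedures are intentionally simple and pluggable: the analysis contract
requires *an* outlier screen and *an* adjustment, not a specific one.

Continent dummies use the alphabetically first level present as the
reference category — an arbitrary but deterministic convention.

Hierarchical control models fit ordered predictor blocks and report each
block's ΔR² and incremental F. Supported orders include covariates-first
(`{wealth, parasite} → {DA, CD} → {DA·CD}`) and the competitive
climate-economic model (`{CD, wealth, CD·wealth} → {DA} → {DA·CD}`). A
predictor column that is identically zero contributes ΔR² = 0 rather than
raising a rank error; genuinely collinear nonzero columns still raise.

Degenerate edge cases: a saturated (noise-free) full model has R² = 1, where
the incremental F is undefined; `fit_moderated` reports it as infinite with
p = 0 rather than failing, since noise-free synthetic data are a supported
validation input. The standalone `delta_f` keeps the strict r² < 1 contract.

## Synthetic generator

One latent factor `u_p ~ N(0, latent_sd²)` per population drives all nine
frequencies: `f_pj = logistic(logit(base_j) + λ_j u_p)`, with the published
mixed-sign loading pattern as the default λ and plausible worldwide mean
frequencies as `base_j`. Configurations whose frequencies are ~0 or ~1 for
every population at some locus are rejected as degenerate. Each population
receives 2–6 literature samples of 50–400 participants; every sample
reports all nine loci (so a sample-level correlation matrix, and hence the
cross-level congruence check, exists) and observes each frequency through
binomial counting noise at `2N` chromosomes. The `freq_noise_sd` dial is a
dispersion multiplier folded into an effective count `2N/φ²`: 1 is the
plain binomial, 0 switches frequency noise off entirely.

Climate is induced by drawing a target demand uniformly over
`climate_range` (default 10–120 °C-degrees, spanning tropical to
continental conditions) and splitting it across the four extremes so the
ordering invariants hold and the demand formula recovers the target
exactly. Wealth and parasite stress are standard-normal composites tuned to
the correlation pattern observed across real nations (wealth: +0.42 with
demand, +0.36 with the index; parasite stress: −0.74 with demand, −0.67
with wealth). Continent labels stratify populations into four contiguous
latent-factor blocks, giving the dummy-code robustness check genuine
structure to absorb.

Trait means follow `Y = β0 + β1·DA + β2·CD + β3·DA·CD + ε`,
`ε ~ N(0, trait_noise_sd²)`, with DA the *true* (noise-free) 0–100 index,
CD the true demand, both mean-centred as in the analysis. The true index is
defined as the noise-free limit of the estimator itself — the full
correlation → smoothing → PCA → orientation → scoring → scaling chain
applied to the true frequency matrix — so that with all noise switched off
the estimated and generating quantities coincide exactly and coefficient
recovery is an identity, not an approximation. Defaults
β = (50, 1.5, 1.0, 0.8) with trait noise SD 5: an intercept mid-scale on a
0–100 trait metric and an interaction strong enough that a 40-population
study detects it with high power. Each of three instrument labels (bfi,
neo, opq) gets an extraversion-like trait (positive dopamine terms) and a
neuroticism-like trait (mirrored signs) with independent noise, emulating
three independent measurement sources of the same constructs.

### What the generator does and does not emulate

It reproduces: heterogeneous sample sizes and counts, binomial frequency
noise, a dominant shared factor with mixed-sign loadings, demand-spanning
climates, covariates with realistic correlations, and interaction-generated
traits. It does **not** emulate: linkage between loci, Hardy–Weinberg
genotype structure, locus-specific population-level variation beyond the
single factor (real inter-locus correlations average ~0.4, the generator's
are near 1, so index reliability is higher here than in real data),
spatial/phylogenetic autocorrelation between neighbouring nations, or
item-level questionnaire psychometrics. Passing tests therefore demonstrate
the correctness and calibration of the *estimation machinery* under the
assumed data-generating process, not the robustness of the scientific
conclusion to violations of that process.

## Problem sizes and numerical choices

Default synthetic studies use 40 populations — the scale of the real
trait-matched analyses (27–38 nations). Monte-Carlo validation uses 500
replicates for the recovery and calibration tests in the suite and 200 in
the acceptance script; at these sizes the binomial 99% acceptance band for
a nominal 5% test is roughly ±2.5 and ±4 percentage points respectively.
PSD floor 1e-6; correlation symmetry tolerance 1e-10; rank checks use
numpy's SVD-based matrix rank; z-scoring uses ddof = 1 throughout. All
randomness flows through `numpy.random.default_rng` seeded from the
configuration, and equal seeds give byte-identical tables.

## Known limitations

- The exact factor-scoring method and the alpha's input scale in the
  original analyses are not documented; the choices here (renormalised
  loading-weighted z-scores; alpha from the smoothed, reflected correlation
  matrix) are explicit and swappable but not certified to match.
- Whether published coefficients sit on the raw 0–100 scale or a
  standardised scale is ambiguous; both are reported.
- Only the first principal component feeds the index; the second and third
  components are reported (eigenvalues, congruence) but unused.
- The outlier screen assumes approximate multivariate normality; with
  population counts under ~30 the χ² reference for Mahalanobis distances is
  itself approximate.
- No spatial or phylogenetic non-independence correction beyond continent
  dummies.
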