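# Methods

`arborclim` asks whether broad-scale climate constrains which species can
occupy the arboreal microhabitat, using two complementary analyses over a
synthetic study system with known ground truth: a multivariate
phylogenetic ANOVA of species climate envelopes on microhabitat type, and
a niche-overlap analysis of pairwise maximum-entropy suitability models.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic world does and does not establish.

## The synthetic world

The generator replaces field data (museum occurrence records, global
climate rasters, a published chronogram, literature-based microhabitat
codes) with a fully specified generative process, so every downstream
statistic can be checked against an injected effect size.

**Climate raster.** Twelve layers (BIO1, BIO5, BIO6, BIO12, BIO16, BIO17,
PET.A, PET.W, PET.D, Elev, CM, CC) on a row-major grid from the
north-west corner, 2.5 arc-minute pixels by default. Independent
standard-normal fields are mixed through a symmetric square root of a
12x12 layer-correlation matrix (default: a two-factor thermal/hygric
structure, which is positive semi-definite by construction), smoothed
with a Gaussian kernel (`smoothing_radius`, default 2 pixels) for spatial
autocorrelation, re-standardized per layer, then scaled to per-variable
baselines chosen to resemble new-world temperate-to-tropical climate
(e.g. BIO1 15 +/- 6 degrees C, Elev 800 +/- 550 m). BIO1 additionally
receives a deterministic, mean-centered latitudinal trend of
`temp_lat_gradient` (default 0.7 degrees C per degree of |latitude|).
Elevation is clipped at zero. Pixel membership uses half-open intervals
[west, east) x (south, north] so every in-extent point maps to exactly
one pixel; sampled occurrences sit at pixel centers.

**Chronogram.** Pure-birth with rate `birth_rate` (default 1 per unit
time), conditioned on the tip count: the process grows to `n_species`
lineages and is cut one further exponential waiting time later, so tree
height is the sum of Exp(k * birth_rate) intervals for k = 2..n. The test
suite verifies the closed-form height expectation by Monte Carlo.

**Microhabitat labels.** A two-state continuous-time Markov chain
(terrestrial <-> arboreal) run along the tree with gain rate 0.3 and loss
rate 0.9 per unit time by default. The loss-biased asymmetry reflects the
empirical pattern that lineages abandon arboreality far more readily than
they acquire it; the default ratio is kept at 3:1 rather than the
extreme estimates reported for real salamanders because a default world
must reliably contain enough arboreal species (>= 2) to be analyzable at
desk scale. Stronger asymmetries are exercised in the tests as explicit
conditions.

**Niche centers.** Brownian motion per climate variable along the tree
(rate `bm_sigma`, default 0.4 of each variable's global SD per unit
time), plus a constant additive offset `arboreal_shift` applied to
arboreal tips. The default shift places arboreal optima in warmer
(+1 SD BIO1/BIO6, +0.7 SD BIO5), lower (-1 SD Elev), higher-PET (+0.4 SD
PET.A) climates. A constant tip-level offset is used rather than a
regime-dependent Ornstein-Uhlenbeck optimum: the downstream analyses test
group mean differences, not evolutionary model fit, and the offset is
the cleanest way to inject a known group-mean signal.

**Occurrences.** Pixels are drawn with probability proportional to a
product-Gaussian suitability of the pixel's climate around the species'
niche center (`niche_breadth`, default 0.6 global SD per variable), with
`points_per_species` uniform in [20, 60] by default. Because sampling is
restricted to climates that exist on the raster, realized species means
shrink toward the available climate; the injected group contrast
survives this shrinkage, which is exactly what the recovery tests check.

What the generator does *not* emulate: coastlines or realistic
topography, georeferencing and identification error in occurrence
records, spatially biased collection effort, and any real covariance
between range size and microhabitat. Passing tests therefore demonstrate
that the estimators recover known effects under a well-behaved sampling
process, not that the real data meet these assumptions.

## Climate envelopes

Occurrences are thinned to one record per species per climate pixel
(first record wins; off-raster records dropped with logged counts),
climate is read from the containing pixel without interpolation, and
species with at least 3 retained pixels are summarized by five statistics
per variable: 5th percentile, 25th percentile, mean, 75th percentile,
95th percentile. Percentiles interpolate linearly between order
statistics (the common default; the choice is a recorded convention, not
derived from any source). The species x 60 matrix is converted to
standard normal deviates column-wise (sample SD, n-1 denominator) before
the joint test and the PCA; per-variable tests use the native-unit
5-statistic blocks. PCA is by SVD of the centered standardized matrix;
each loading vector's largest-magnitude entry is made positive so signs
are reproducible run to run.

## Phylogenetic ANOVA with randomized residual permutation

Under Brownian motion the expected covariance of tip values is C, with
C[i,j] the root-to-MRCA path length. Responses and design are whitened by
the inverse symmetric square root of C (eigen-factorization, eigenvalue
floor 1e-12 relative to the largest; a near-singular C aborts with a
near-duplicate-tips diagnostic), after which ordinary least squares
equals GLS. The test statistic is the trace-form multivariate F: the
trace of the model SSCP over the trace of the residual SSCP, each scaled
by its degrees of freedom.

Significance comes from the randomized residual permutation procedure:
residuals of the intercept-only reduced model are row-shuffled (999
random permutations by default, plus the observed arrangement),
pseudo-responses are refit under the group model, and
p = #(F* >= F_obs) / (n_perm + 1) with the observed arrangement included.
Because both SSCP projectors annihilate the reduced-model fit, the
permuted statistic depends only on the shuffled residuals, which is what
the vectorized implementation computes. Statistics within a relative
1e-9 of the observed value count as ties (symmetric arrangements
reproduce the observed statistic up to floating-point noise; without the
guard, exhaustive-enumeration p-values drift below the exact value).

The effect size Z standardizes the observed statistic against the
permutation distribution on the log scale (F-type statistics are
right-skewed under permutation; a raw scale is available via
`stat_scale="raw"`). Pairwise group contrasts use the Euclidean distance
between GLS group means under the same permutation schedule, and a
contrast is flagged significant when Z exceeds 1.645, the one-sided
standard-normal critical value. Multiple testing within the five-PC
family and within the twelve-variable family uses Holm's sequential
Bonferroni: rank-k threshold alpha/(m - k + 1), ascending-p order stable
on ties, first failure blocking later ranks. Robustness to phylogenetic
uncertainty is summarized by the 2.5%/97.5% quantiles of Z across a
posterior sample of chronograms (synthetically emulated by lognormal
node-age jitter when no real posterior exists); per-tree seeds derive
from one master seed.

## Maximum-entropy niche models

Each species with at least 15 distinct presence pixels gets a
presence-background Gibbs model over the raster's valid pixels:
p(x) proportional to exp(w . f(x)), with f(x) the per-variable linear and
quadratic terms standardized by background mean and SD (24 features). The
weights minimize the penalized negative average presence log-likelihood;
the problem is convex and solved by L-BFGS from a zero start, so the fit
is deterministic and needs no seed. An L2 penalty (default 0.01) is used
instead of the L1 regularization of classical MaxEnt software — simpler
optimization, equivalent role; hinge/threshold features and output
transforms are out of scope. The background is the full set of valid
raster pixels. Fit quality is the presence-background AUC (rank
formulation, ties at 0.5), and non-converged fits (gradient norm above
tolerance) propagate a warning into the overlap stage.

## Niche overlap and the pair-type test

Projected suitability surfaces are normalized to sum to one over valid
pixels. For each unordered pair of arboreal/terrestrial species:
Schoener's D = 1 - 0.5 * sum|p - q| and Warren's
I = 1 - 0.5 * sum(sqrt(p) - sqrt(q))^2, both in [0, 1], computed over the
full shared raster (recorded in table metadata; a per-pair union extent
is a possible alternative nobody has shown to matter here). Geographic
distance is the WGS84 geodesic between the species' mean post-pruning
occurrence points, computed by Vincenty's inverse iteration (tolerance
1e-12, 200 iterations, spherical haversine fallback for the
near-antipodal non-convergent case and as an explicit `ellipsoid="sphere"`
option). Phylogenetic distance is C_ii + C_jj - 2 C_ij, the patristic
distance on ultrametric trees.

Each overlap metric (D and I are tested separately) is regressed by OLS
on intercept, geographic distance and phylogenetic distance; designs with
condition number above 1e10 abort with a collinearity diagnostic. The
residuals are tested across AA/AT/TT pair types by one-way permutation
ANOVA (999 row shuffles by default) with three pairwise mean-difference
contrasts on the same schedule, Z and p as in the comparative arm.
Pairs sharing a species remain non-independent beyond what the two
distance covariates absorb; the default free row permutation ignores
this (the result metadata says so), and a Mantel-style species-level
permutation mode (`mode="species"`) is provided as a conservative
alternative, off by default.

## Problem sizes and runtime choices

The packaged study world uses 60 species on a 60x60 raster with 20-60
points per species; calibration suites use 1000 replicate 40-tip null
worlds at 499 permutations, and recovery suites use 100 replicate
worlds. These sizes were chosen so the full analysis and test suite run
in minutes on one CPU while leaving Monte-Carlo error well inside the
asserted bands (a rejection-rate SE of ~0.007 at 1000 replicates against
a +/-0.02 band). The permutation engine is vectorized across the whole
schedule, which is what makes the calibration suites cheap.

## Known limitations

* The pair-type test inherits the pairwise non-independence caveat above.
* The maximum-entropy model is a documented stand-in for MAXENT-class
  software, not a reconstruction of any particular version's feature set.
* The posterior-chronogram sample is a branch-length jitter, not a real
  Bayesian posterior; it exercises the robustness machinery, nothing more.
* Envelope summaries assume the 12 configured variables; variable
  selection (e.g. autocorrelation screening) is configuration, not
  computation.
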