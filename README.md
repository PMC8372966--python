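# arborclim

Does broad-scale climate constrain which species can live in trees?
`arborclim` implements, end to end, the comparative analysis behind that
question for clades like lungless salamanders, where arboreality appears
and disappears repeatedly without morphological specialization: if the
arboreal microhabitat is only viable under particular climates (warm,
low-elevation, humid), arboreal species' climate envelopes should differ
predictably from terrestrial ones, and arboreal species' niches should
overlap each other more than they overlap terrestrial niches.

The package is built for methodologists and students of phylogenetic
comparative methods: every stage runs on a synthetic world with known,
configurable effect sizes, so estimator behavior (type-I error, power,
recovery of injected effects) can be measured rather than assumed.

## What it computes

Two complementary analysis arms over shared inputs (occurrence records,
a 12-layer climate raster, a time-calibrated phylogeny, microhabitat
codes):

1. **Phylogenetic comparative arm.** Occurrences are thinned to one
   record per climate pixel; species with >= 3 pixels get a climate
   envelope of five statistics (5th, 25th percentile, mean, 75th, 95th
   percentile) per variable. Microhabitat differences are tested by
   multivariate phylogenetic ANOVA: responses whitened by the inverse
   square root of the Brownian covariance C (so OLS = GLS), trace-form F,
   and significance by the randomized residual permutation procedure
   (RRPP) — reduced-model residuals are row-shuffled and the observed
   statistic is located in the refit distribution, with effect size
   Z = (log F_obs − mean log F*) / sd(log F*). Tests run on all 60
   standardized statistics jointly, on the first five PC axes, and on
   each variable's 5-statistic block, with Holm sequential Bonferroni
   (rank-k threshold α/(m−k+1)) inside the PC and per-variable families.
2. **Niche-overlap arm.** Species with >= 15 distinct presence pixels get
   a presence-background maximum-entropy suitability model (linear +
   quadratic features, L2 penalty, convex deterministic fit) projected
   over the raster. Every arboreal/terrestrial species pair gets
   Schoener's D = 1 − ½Σ|p−q| and Warren's I = 1 − ½Σ(√p−√q)², the
   WGS84 geodesic between mean occurrence points, and the phylogenetic
   distance C_ii + C_jj − 2C_ij. Each overlap metric is regressed on the
   two distances and the residuals are tested across AA/AT/TT pair types
   by permutation ANOVA with pairwise contrasts.

The synthetic world supplies all inputs: spatially autocorrelated,
cross-correlated climate layers with a latitudinal temperature gradient;
a pure-birth chronogram; arboreal/terrestrial labels from an asymmetric
two-state Markov process; Brownian niche centers with an additive
arboreal shift; and occurrences sampled from Gaussian niche suitability.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
packaged synthetic world (60 species, 60x60 raster, seeded):

```bash
python analysis/01_simulate_world.py
python analysis/02_classify_microhabitats.py
python analysis/03_climate_envelopes.py
python analysis/04_phylogenetic_anovas.py
python analysis/05_niche_models_overlap.py
```

The comparative driver prints the pairwise arboreal-vs-terrestrial table
(excerpt):

```
Variable         Z     P    Alpha  Significant
     All  5.343626 0.001 0.050000         True
     PC1  2.309750 0.001 0.010000         True
    BIO1  3.378373 0.001 0.004167         True
    BIO6  3.199566 0.001 0.005000         True
    Elev  3.334269 0.001 0.007143         True
significant after sequential Bonferroni: ['All', 'PC1', 'BIO1', 'BIO5', 'BIO6', 'BIO16', 'PET.A', 'PET.W', 'Elev']
posterior-tree Z interval for the A-vs-T contrast: [5.320, 5.748] (cutoff 1.645)
```

Each row is one phylogenetic ANOVA: Z is the RRPP effect size, P the
permutation p-value, and Alpha the Holm threshold it is compared against
(0.0042 = 0.05/12 for the best-ranked of the twelve variable tests). The
generator placed arboreal niche optima in warmer, lower climates, and
exactly those variables (BIO1/BIO5/BIO6, Elev, PET) come out significant
— the pipeline recovers the injected effect. The ENM driver then reports:

```
53 species modelled; AUC range 0.985-0.998
1378 species pairs; geographic distances 0.4-132.6 km
D: overall Z=4.053 p=0.0010 (AA-AT: Z=2.36 p=0.001, AA-TT: Z=1.67 p=0.003, AT-TT: Z=2.89 p=0.001)
```

i.e. after adjusting overlap for geographic and phylogenetic distance,
mixed arboreal-terrestrial pairs overlap least — niche space separates
the two microhabitats.

A thin CLI wraps the same library (`arborclim simulate | classify |
summarize | panova | enm | overlap via pairtest | all`); see
`arborclim --help`.

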