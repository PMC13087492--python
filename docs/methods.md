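# Methods

`multitroph` analyses how two trophically linked guilds — fish and
crustacean zooplankton — co-respond to environmental gradients in a lake
metacommunity, and how their co-occurrence structure and community trait
composition are expected to shift under warmer climates.  This note
documents the models, the defaults and the reasoning behind the design
choices; it is the companion to the API documentation in the docstrings.

## Diversity statistics

Per-site richness is a row sum of the binary occurrence matrix, computed
per guild.  Site uniqueness is measured by the local contribution to
beta diversity (LCBD): with `D` the pairwise Jaccard dissimilarity matrix
on presence-absence data, the Gower-centred matrix of `-D^2/2` is formed
and site *i*'s LCBD is its diagonal element divided by the total sum of
squares.  LCBD values are non-negative and sum to 1 across sites.

Significance is assessed by a permutation test that shuffles every
species column independently (999 permutations by default), with
`p = (#{LCBD* >= LCBD} + 1) / (n_perm + 1)`, followed by a Holm step-down
correction across sites; fish and zooplankton are treated as separate
families because the two uniqueness questions are distinct.  The
richness–LCBD relationship is fitted by OLS in linear and quadratic form;
the retained form is chosen by **adjusted** R² (the quadratic nests the
linear model, so raw R² would always pick it), with ties going to the
linear form.  Raw-R² selection is available as an option.

## Variable screening

One random-forest classifier per species ranks environmental covariates.
For each species we record the out-of-bag (OOB) misclassification rate
and the classic Breiman OOB permutation importance (per tree: accuracy on
the tree's OOB rows minus accuracy after permuting one covariate among
those rows, averaged over trees).  Global importance is the across-species
average weighted by `w_s = max(0, 1 - oob_error_s)`, so unpredictable
species contribute little; weighting by error instead is a config switch.
The top-k covariates (default 10) are retained, after which an exclusion
list removes covariates destined for random effects (raw coordinates).
Conditional permutation importance is not implemented; importances of
correlated covariates should be read with the usual caution — the
collinearity screen (drop one member of any pair with |Pearson r| > 0.9,
later-listed member goes) runs first and limits the issue.

Each species' forest draws from an RNG stream keyed by the species
identifier, so the global ranking does not depend on table column order.

## The joint species distribution model

Occurrence is modelled as a multivariate probit with a trait hierarchy
and latent factors:

    y_ij = 1[z_ij > 0]
    z_ij = x_i' beta_j + sum_h eta1_ih lam1_hj + sum_h eta2_ih lam2_hj + eps_ij
    beta_j ~ N(Gamma' t_j, V),   eps_ij ~ N(0, 1)

* `beta` (K x S): species-environment coefficients on the standardised
  design (intercept included).
* `Gamma` (Q x K): trait-environment effects; the trait design holds an
  intercept, z-scored log continuous traits (body length, CTmax) and
  dummy-coded categorical traits.
* `V` (K x K): residual niche covariance among species after traits.
* Site factors `eta1` are i.i.d. standard normal with loadings `lam1`;
  spatial factors `eta2` follow a Gaussian process with exponential
  correlation `exp(-d/alpha_h)` on Euclidean distance in decimal degrees,
  with `alpha_h` (the spatial range, in degrees) sampled on a discrete
  grid of 101 values from 0 to the maximum pairwise site distance.
* Loadings carry multiplicative-gamma shrinkage priors
  (`a1 = a2 = 5`), so unneeded factors are damped; factor counts are
  fixed (defaults: 2 site, 4 spatial) rather than adapted.

Priors: `Gamma ~ N(0, 10)` elementwise; `V ~ InvWishart(K + 2, I)` so the
prior mean of `V` exists and equals the identity.  All are configurable
and recorded with the posterior.

### Inference

Gibbs sampling with truncated-normal data augmentation of the probit
liabilities.  All updates are conjugate (liabilities, `beta` jointly per
species with a shared Cholesky, `Gamma` via a KQ-dimensional normal
solve, `V` via inverse-Wishart, loadings and factors via normal solves)
except the spatial ranges, drawn from their discrete conditional
posterior using precomputed inverses and log-determinants per grid value.
Chains are seeded from a spawned `SeedSequence`, making runs bit-identical
under a fixed seed.  A `likelihood=False` switch makes the augmentation
draw liabilities from the model instead of conditioning on the data; the
chain then targets the prior exactly, which the test suite uses as a
prior-reproduction check.  `fixed_gamma` / `fixed_v` switches support the
brute-force posterior comparison on tiny problems.

Convergence is summarised by the classic split-chain potential scale
reduction factor for every `beta` and `gamma` element (each chain split
in half; PSRF = sqrt(((n-1)/n W + B/n)/W)), plus effective sample sizes.

### Posterior summaries

* **Tjur R²** per species: mean fitted probability at presences minus at
  absences, using conditional fitted probabilities averaged over draws.
* **Sign support**: per element, `max(P(>0), P(<0))` over draws; heatmap
  exports mask elements at support <= 0.90 for `beta`/`gamma` and <= 0.95
  for residual associations.
* **Residual associations**: per draw `Omega = Lambda' Lambda + I` (the
  identity is the probit noise floor), converted to a correlation matrix;
  `Omega` rather than `Lambda` is summarised because it is invariant to
  factor rotation and label switching.  Retained pairs are tabulated by
  guild pairing with positive/negative percentages.
* **Variance partitioning**: per draw and species, the fixed-effect
  contribution of covariate group *g* is `sum_{k in g} sum_{k'}
  cov(X)_{kk'} beta_k beta_k'` (covariance terms split evenly between the
  two groups involved; the occasional negative split is clipped at zero),
  random-effect contributions are `sum_h lam_hj^2` per factor block;
  fractions are normalised per draw, averaged, and multiplied by the
  species' Tjur R² to give absolute explanatory shares.  The intercept
  contributes nothing on a standardised design and is excluded from the
  named groups.

### MCMC schedule

The full-length schedule (thin 5, 1000 retained per chain, 2 chains,
transient 2500) is the default of `MCMCConfig`.  Desk-scale work —
everything the test suite and the acceptance script run — uses 2 chains x
500 retained at thin 2 with transient 1000, following the rule
transient = 500 x thin.  At the default synthetic dimensions (150 sites,
30 species, 5 covariates, 2 + 4 factors) one fit takes ~25 s on one CPU
and reaches max split-PSRF ~= 1.06-1.09.

## Scenario projection

A scenario table replaces climate-class covariates with shifted values
(e.g., GCM-style warming for 2081-2100); morphometry is untouched.
Scenario columns are standardised with the **baseline** transform
parameters — the preprocessor is fitted once and reused, never refitted.
Predictions average probabilities (not liabilities) over posterior draws.
Two modes:

* `conditional` (default): reuse the estimated site/spatial factor scores
  — the right choice when predicting at the training lakes, which is what
  scenario comparison at fixed sites needs;
* `marginal`: integrate factors over their prior,
  `Phi(x'beta / sqrt(1 + sum_h lam_hj^2))`, for new sites.

The projection inherits the usual caveats: species pools are fixed, traits
are fixed within species, and dispersal is implicitly unlimited.

## Co-occurrence networks

For every species pair, Spearman's rank correlation across sites of the
posterior-predictive probabilities, two-sided p from the t-approximation
with n-2 degrees of freedom; pairs with p < 0.01 (uncorrected, by design)
become signed edges.  Topology metrics are computed on the unweighted,
sign-agnostic graph restricted to edge-incident species: connectance
(edge density), mean shortest-path length over reachable ordered pairs,
communities from the Girvan-Newman edge-betweenness dendrogram cut at the
partition maximising modularity (the trivial single-community partition
is a candidate, so a complete graph reports Q = 0), and that partition's
modularity.  Singleton components count as communities; isolated species
are listed but not counted as nodes.  Scenario networks are compared to
baseline as edge sets (gained / lost / retained, sign flips flagged).

## Community-weighted means

`CWM_i = sum_j p_ij t_j / sum_j p_ij` for continuous traits; categorical
traits yield per-level proportions under the same weights.  CWMs are
computed per guild.  Trait-climate trends are straight OLS fits of the
CWM on the raw (unstandardised) covariate per scenario; the slope sign
and magnitude are the comparable quantities, any smoothing is left to
plotting.  A per-site summary (expected richness `sum_j p_ij`,
probability-weighted mean length, richness split at a 0.5 mm length
cutoff — the conventional small/large zooplankton boundary) supports the
richness-vs-temperature reading of length trends.

## Synthetic metacommunities

The generator emulates a boreal-temperate lake survey: 150 sites spanning
17 degrees of latitude (default; a 156-site survey-scale shape is a flag
away), 18 fish + 12 zooplankton species, air-temperature covariates
declining with latitude, precipitation varying along an independent
longitudinal axis (inland-maritime contrast), lognormal lake area,
lognormal body lengths (fish log-sd 1.1, roughly 50 mm to 1 m; zooplankton
around 1 mm), CTmax near 30 C, and categorical trophic-group and habitat
traits.  Occurrences are drawn from exactly the model the pipeline fits,
so every recovery test has a known truth.

Default planted effects (all on the z-scored trait design):
`gamma(intercept, max_temp) = 0.5` (communities richer in warm lakes),
`gamma(length, max_temp) = -0.8` (large-bodied species respond less
positively to warmth — the temperature-size expectation),
`gamma(ctmax, min_temp) = 0.6`, `gamma(length, precipitation) = -0.5`;
residual niche covariance `V = 0.05 I`; one site factor with loadings
+-1.2 planting three positive/negative fish-zooplankton residual pairs;
one weak spatial factor (loading sd 0.25, range 5 degrees).  Effect sizes
were chosen once so each planted signal is detectable at desk scale —
in particular the length-temperature effect must exceed the niche noise
within the fish guild after cross-guild trait standardisation, which
pins it at the strong end of the plausible range.  Species with simulated
prevalence 0 or 1 trigger a full resample from a spawned seed (bounded
attempts).

`SimConfig.network_scenario()` is a second documented structure used for
climate-compression experiments: two niche modules (thermal littoral
species vs precipitation-driven pelagic species, both mediated by the
habitat trait) plus a common site-quality factor every species loads on
(+0.35).  Under a gradient-compressing warming (larger deltas at colder
sites), the thermal module loses its dominant driver, the shared axis
takes over site orderings, and cross-module correlations rise above the
significance threshold: connectance increases and modularity decreases —
the homogenisation signature expected when northern communities converge
on southern ones.  Rank correlations are invariant to per-species
monotone shifts, so this latent-structure route is the mechanism by which
a probability-matrix network can homogenise at fixed sites.

### What the generator does not emulate

Real surveys bring detection error, abundance information collapsed to
presence-absence, trait measurement error, phylogenetic signal,
non-linear niches (optima rather than monotone responses), and covariate
maps far rougher than smooth latitudinal gradients.  Passing recovery
tests on these simulations therefore demonstrates that the estimator and
pipeline are correct and well calibrated under the model's own
assumptions — not that the model is adequate for any particular survey.

## Numerical choices

* Truncated-normal draws by inverse-CDF with arguments clipped to
  [1e-12, 1 - 1e-12]; a non-finite liability aborts with a diagnostic.
* Spatial correlation matrices get 1e-8 jitter before Cholesky.
* Collinearity ties: the later-listed covariate of a flagged pair drops.
* Imputation of missing covariate cells: single-pass column median
  (mean optional) — deterministic and sufficient for the few missing
  values this pipeline expects; multiple imputation is out of scope.
* Missing continuous traits: group-mean imputer (overall mean fallback).
* Degenerate inputs raise typed `ValidationError`s naming the offending
  rows/cells rather than propagating NaNs.

## Known limitations

* Probit link only; no abundance models; no phylogenetic term.
* Factor counts are fixed, not adapted; heavily factor-structured data
  may need the counts raised.
* Girvan-Newman is O(m^2 n); for networks beyond a few thousand edges
  compute budget grows quickly.
* Conditional scenario predictions hold factor scores fixed, which is
  exactly right at training sites but transfers residual structure
  unchanged into scenarios.
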