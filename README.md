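# multitroph

Multi-trophic metacommunity analysis for presence–absence surveys of two
trophically linked guilds (fish and zooplankton) along environmental
gradients: diversity and site-uniqueness statistics, random-forest
variable screening, a trait-structured latent-factor joint species
distribution model (JSDM) fitted by Gibbs sampling, posterior-predictive
projection under climate scenarios, significance-filtered co-occurrence
networks, and probability-weighted community trait means.

It is aimed at community ecologists who have site × species occurrence
tables, site × covariate environmental tables (baseline plus
climate-scenario variants) and species × trait tables, and who want the
whole chain — from uniqueness maps to "what does the co-occurrence
network look like in 2100" — in one tested pipeline with a known-truth
simulator for validation.

## The model at the core

Occurrence of species *j* at site *i* is multivariate probit with a trait
hierarchy and latent factors:

```
y_ij = 1[z_ij > 0]
z_ij = x_i' β_j + Σ_h η1_ih λ1_hj + Σ_h η2_ih λ2_hj + ε_ij,   ε_ij ~ N(0,1)
β_j ~ N(Γ' t_j, V)
```

where `β` are species–environment responses, `Γ` the trait–environment
effects (how body length, thermal tolerance or trophic group bend a
species' niche), `V` the residual niche covariance, `η1`/`λ1` i.i.d. site
factors, and `η2`/`λ2` spatial factors with exponential distance decay
`exp(−d/α_h)` whose ranges `α_h` (degrees) are sampled over a discrete
grid.  `Ω = Λ'Λ + I` on the correlation scale gives residual
species-pair associations — co-occurrence beyond shared environmental
responses.  Posterior summaries include Tjur R², sign-support-filtered
`β`/`γ` heatmaps (support > 0.90), residual associations (support >
0.95), and Tjur-adjusted variance partitioning.  Site uniqueness uses
LCBD (per-site share of total Jaccard β-diversity) with per-column
permutation tests and Holm correction.  Scenario networks connect species
pairs whose posterior-predictive occurrence probabilities have Spearman
p < 0.01 across sites.

See `docs/methods.md` for assumptions, priors, defaults and limitations.

## Worked example

```python
import numpy as np
from multitroph import (SimConfig, generate_metacommunity, JointSpeciesModel,
                        PipelineConfig, predict_occurrence, support_filter,
                        residual_associations, correlation_network,
                        network_metrics, cwm, trait_climate_trend)
from multitroph.data_io import preprocess_env

community, env, traits, truth = generate_metacommunity(SimConfig(seed=1))
env_std, prep = preprocess_env(env, PipelineConfig())

model = JointSpeciesModel(thin=2, samples=500, n_chains=2, transient=1000,
                          random_state=1).fit(env_std, community, traits)
post = model.posterior_

beta_hat = post.beta.mean(axis=0)
names = ["intercept"] + prep.kept_covariates_
r = np.corrcoef(beta_hat.ravel(),
                truth.beta_true.loc[names].to_numpy().ravel())[0, 1]
print(f"corr(true beta, posterior mean) = {r:.3f}")

gamma = support_filter(post, "gamma", 0.90)
print(f"gamma(length, max_temp) = "
      f"{gamma.posterior_mean.loc['length', 'max_temp']:.2f} "
      f"(support {gamma.support.loc['length', 'max_temp']:.2f})")

prob = predict_occurrence(post, env_std)          # baseline probabilities
net = correlation_network(prob, alpha=0.01, guild=community.guild)
m = network_metrics(net)
print(f"network: {m.n_nodes} nodes, {m.n_edges} edges, "
      f"connectance {m.connectance:.2f}, modularity {m.modularity:.3f}")

table = cwm(prob, traits, guild="fish", guild_labels=community.guild)
trend = trait_climate_trend(table.continuous["length"], env, "max_temp")
print(f"fish length CWM slope vs max_temp: {trend.slope:.2f} mm/degC")
```

Output:

```
corr(true beta, posterior mean) = 0.962
gamma(length, max_temp) = -0.82 (support 1.00)
network: 30 nodes, 352 edges, connectance 0.81, modularity 0.019
fish length CWM slope vs max_temp: -0.97 mm/degC
```

Read: the sampler recovers the planted species–environment coefficients
almost exactly (r = 0.96); the planted negative length–temperature trait
effect is detected with full posterior support; the baseline network of
this strongly gradient-driven synthetic community is dense and
unstructured; and warm lakes carry smaller-bodied fish communities
(negative CWM slope), consistent with the planted trait effect.

## Command line

```
multitroph simulate   --seed 1 --outdir data/            # synthetic dataset
multitroph validate   --community data/community.csv
multitroph diversity  --community data/community.csv --outdir out/
multitroph select-vars --community data/community.csv --env data/env.csv --outdir out/
multitroph fit        --community data/community.csv --env data/env.csv \
                      --traits data/traits.csv --config cfg.yaml --outdir out/
multitroph project    --posterior out/posterior --env scenario_env.csv --outdir out/
multitroph network    --prob out/prob_baseline.csv --outdir out/
multitroph cwm        --prob out/prob_baseline.csv --traits data/traits.csv --outdir out/
```

Every run writes a `run_manifest.json` with the seed, config hash and
library versions.

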