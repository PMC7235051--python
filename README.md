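# dyadconflict

A Bayesian analysis pipeline for parent–adolescent conflict in dyadic family
data: which parental characteristics — interpersonal-circumplex problems
(agency, communion, elevation) or depressive symptoms — best predict the
conflict their adolescent reports?

It is written for researchers working with clustered questionnaire data from
families: each adolescent reports conflict with each participating parent on
16 true/false items (CBQ, Perception of the Dyad), while parents self-report
interpersonal problems (IIP-C, 32 ordinal items over 8 circumplex octants)
and depressive symptoms (17 SCL-90-R items).

## The model

Conflict is never observed directly; the 16 dichotomous items measure a
latent per-dyad conflict level θ through a two-parameter logistic item
response model, estimated jointly with a multilevel robust regression:

```
y_dj | θ_d          ~ Bernoulli( logit⁻¹( α_j (θ_d − β_j) ) )      (measurement)
θ_d  | x_d, u_f(d)  ~ Student-t( ν, x_d'b + u_f(d), σ )            (structure)
u_f                 ~ Normal(0, τ)                                  (family)
```

with weakly informative priors: b ~ N(0,1); α_j ~ Gamma(2, 0.5) on (0, 10];
β_j ~ N(μ_β, σ_β) hierarchically; σ, τ, σ_β ~ half-t(3,0,1); ν−1 ~
Gamma(2, 0.1). The Student-t likelihood with estimated ν makes the slope
robust to outlying dyads. Whole-scale-missing predictors are imputed inside
the model via a multivariate normal over (agency, communion, elevation,
depression). Four pre-registered regressions are compared — depressive
symptoms with/without a parent-gender interaction (M1, M2) and circumplex
problems with/without the interaction (M3, M4), all with adolescent age
centred at 15 — by **exact leave-one-family-out cross-validation** (one
refit per family per model) and **stacking** of the pointwise log predictive
densities.

Everything upstream is included: circumplex scoring (octant means,
norm-table z-scoring, projection onto agency = ¼Σ z·sin, communion =
¼Σ z·cos, elevation = mean z), two-way imputation of item-level missingness
(person mean + item mean − grand mean) with a multiple-imputation stability
diagnostic, and a synthetic-study generator with known ground truth that
emulates the dyadic design (60 families, ≈100 parents, realistic predictor
correlations and missingness).

Posteriors are sampled with an in-package No-U-Turn sampler over
analytically differentiated log posteriors (a numba kernel; the pure-numpy
reference implementation is kept and tested against it).

## Worked example

```python
import warnings
from dyadconflict import (SimulationConfig, generate_dataset, synthetic_norms,
                          score_parents, build_predictor_matrix, dyad_item_matrix,
                          ModelSpec, SamplerConfig, fit_joint, report,
                          predictor_correlations)

cfg = SimulationConfig(n_families=60, seed=100)      # study-scale synthetic data
dataset, truth = generate_dataset(cfg)
scores = score_parents(dataset, synthetic_norms(cfg), seed=100)
matrix = build_predictor_matrix(dataset, scores)
sampler = SamplerConfig(chains=2, warmup_iterations=500,
                        sampling_iterations=500, seed=100)
post = fit_joint(ModelSpec("M3_interpersonal"), matrix,
                 y_items=dyad_item_matrix(dataset), sampler=sampler)
print(report(post).round(2))
```

prints (columns abridged):

```
                                     mean     sd     ess  rhat
parameter
Agency                               0.26   0.14  267.77  1.01
Communion                            0.10   0.12  618.27  1.01
Elevation                           -0.00   0.12  799.89  1.00
Adolescent age                      -0.04   0.09  487.90  1.00
Variance of errors                   0.61   0.35   54.54  1.02
Variance of random effects           0.64   0.42   93.53  1.02
Degrees of freedom in t-likelihood  22.61  14.22  975.65  1.00
```

The generator injected a standardized agency effect of 0.2 (communion 0,
elevation 0.1); the posterior mean of 0.26 with SD 0.14 recovers it within
posterior uncertainty, and communion/elevation stay near zero. The variance
rows are the posteriors of σ² and τ²; ν ≈ 23 says this replicate needed
little robustness. `predictor_correlations(post)` summarizes the posterior
correlation matrix of the four predictors — e.g. depression–elevation 0.53
(93% CI 0.38–0.65) against a generating correlation of 0.58.

The same pipeline runs from the shell:

```
dyadconflict simulate config.yaml data/
dyadconflict score config.yaml
dyadconflict fit config.yaml --model M3_interpersonal --out posterior/
dyadconflict loo config.yaml --out loo/
dyadconflict stack --pointwise loo/pointwise_lpd.csv --out loo/
dyadconflict report config.yaml --icc
```

Each command logs the config hash and seed; `loo` writes the pointwise
log-predictive-density matrix and a refit manifest, `stack` the comparison
table (ELPD difference to the best model, its standard error, stacking
weight).

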