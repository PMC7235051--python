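# Methods

This note documents the statistical machinery of `dyadconflict`: the joint
model and its priors, the scoring and imputation conventions, what the
synthetic-data generator does and does not emulate, the sampler and its
numerical choices, cross-validation and stacking, and known limitations.

## Design and data model

The unit of analysis is the parent–adolescent dyad. Families contribute one
adolescent (13–17 years) and one or two parents; each parent forms exactly
one dyad with the adolescent. Three tables (adolescents, parents, dyads)
carry the raw item responses; missing cells are explicit (empty or `NA` on
disk, `NaN` in memory) and are never silently filled. Identifiers are opaque
strings. `validate_dataset` checks every structural invariant
(cardinalities, referential integrity, item ranges, whole-scale
missingness) and reports machine-readable issue codes rather than raising.

Conflict items are analysed with 1 keyed toward conflict. Translated forms
with reverse-worded items declare a per-item keying map (+1/−1) in the
config (`apply_cbq_keying`); the default map is all-positive, which is an
assumption, since published forms do not all agree on item wording.

## Scale scoring

**Circumplex scores.** The 32 IIP-C items map to eight octants, four items
each, in fixed blocks of the item order by default (the true item→octant map
of any given form is a config input; published forms differ and no map is
assumed). Octant scores are item means (0–4). They are z-scored against a
norm table — per-octant normative means and SDs, supplied by the user for
real data; a synthetic table derived from the generator's own marginals is
used otherwise and is labelled synthetic. The standardized profile
z₁..z₈ is projected with the warm pole (LM) at 0° and the dominant pole
(PA) at 90°, octants every 45° counterclockwise:

    elevation = mean(z),  agency = ¼ Σ z_i sin(angle_i),  communion = ¼ Σ z_i cos(angle_i).

The ¼ scaling makes a unit-amplitude cosine profile score amplitude 1; with
it, a profile z_i = A·cos(angle_i − δ) scores agency = A·sin δ and
communion = A·cos δ exactly (a tested identity). Standardization is applied
at octant level before projection; whether it should instead be applied to
the three final factors is not determinable from the instruments'
documentation, and octant-level is the package's documented assumption.

**Depression.** The 17-item revised SCL-90-R depression subscale is scored
as the mean item response (range 1–5).

**Two-way imputation.** Item-level missingness is singly imputed before
scoring with the single-pass two-way formula over observed cells,

    x̂_ij = person_mean_i + item_mean_j − grand_mean,

optionally plus Normal(0, s_r) noise where s_r is the SD of observed-cell
residuals under that fit (the stochastic variant used for multiple
imputation), and optionally rounded to the nearest legal scale point. The
deterministic, rounded variant is the default on real data. Note the
single-pass fit is exact for additive matrices only when the deleted cell's
row and column effects equal the means of the remaining ones; iterating the
fit to convergence would be exact for all additive matrices but is a
different (and not the implemented) estimator.

The stability diagnostic re-imputes stochastically `n_imputations` times
(default 1000; tests and the acceptance script use 100–400 for speed) and
reports the per-respondent SD of any summary score across completions;
respondents with no missing items get exactly 0.

## The joint model

For dyad d (family f(d), items j = 1..16):

    y_dj ~ Bernoulli-logit( α_j (θ_d − β_j) )
    θ_d ~ Student-t( ν, m_d, σ ),  m_d = x_d'b (+ intercept) + u_f(d)
    u_f ~ Normal(0, τ)

Priors: coefficients and intercept N(0,1); α_j ~ Gamma(2, 0.5) truncated to
(0, 10] (discrimination beyond 10 is practically a step function); β_j ~
N(μ_β, σ_β) with μ_β ~ N(0,3), σ_β ~ half-t(3,0,1); σ, τ ~ half-t(3,0,1);
ν = 1 + g with g ~ Gamma(2, 0.1), keeping ν ≥ 1. Dyads whose entire item
vector is missing remain in the model with θ informed only by the
regression.

**Identification.** The regression distribution is θ's sole generative
prior by default. An additional standard-normal anchor on θ
(`theta_anchor=True`) is available; it pins the latent scale but combines
two densities on θ and, on data generated at the study's scales, shrinks θ
— and with it every coefficient — by roughly a factor of two, so it is off
by default. Without the anchor the latent scale is identified softly,
through the priors on α, σ and τ; posterior scale estimates can drift
upward when an item bank happens to be weakly informative.

**Missing predictors.** The four continuous predictors (agency, communion,
elevation, depression — standardized within sample) follow a joint
multivariate normal whose mean gets N(0,1) priors and whose covariance is
parameterized by its Cholesky factor (half-t(3,0,1) on diagonal entries,
N(0,1) off-diagonal) — the predictor-model priors are the package's choice,
as only the multivariate-normal form itself is part of the design.
Whole-scale-missing entries are parameters of this block; gender and age
are always observed, and a dummy cannot be normal, so they stay outside it.
Posterior correlations of the predictor matrix are read off the covariance
draws.

**Model specifications.** M1: depression + age. M2: intercept + depression
+ mother dummy + depression×mother + age. M3: agency + communion +
elevation + age. M4: intercept + the three circumplex predictors + mother +
three interactions + age. Father-adolescent dyads are the reference
category. M1/M3 omit the intercept (standardized outcome and predictors);
the dummy-coded M2/M4 need one.

## Sampling

Posteriors are drawn by an in-package No-U-Turn sampler: multinomial NUTS
with biased progressive subtree sampling, dual-averaging step-size
adaptation, and windowed diagonal mass-matrix estimation (initial buffer,
doubling windows, terminal buffer). Divergences are flagged at a
Hamiltonian error of 1000; post-warmup divergence counts are reported per
chain. The log posterior and its gradient are derived analytically on an
unconstrained vector (log transforms for scales with Jacobians, a scaled
logit for the capped discriminations, non-centered parameterizations for
the random intercepts and item difficulties) and implemented twice: a pure
numpy reference and a numba kernel used in production; tests assert the two
agree to ~1e-8 and that the reference matches finite differences.

Defaults mirror the reported estimation settings: 4 chains, 1000 warmup,
3500 draws, target acceptance 0.9. The test and acceptance profile is 2
chains × (500 warmup + 500 draws), which on this model yields bulk ESS of
roughly 200–1000 for regression coefficients. Convergence is declared at
rank-normalized split R-hat ≤ 1.01 and bulk ESS ≥ 400 per regression
parameter; failures warn (and are recorded) rather than raise. A
`--classic-rhat` style option (`classic=True`) computes the original
Gelman–Rubin form.

## Cross-validation and stacking

The cluster is the family. For each model and family, the model is refit on
all other families (refit seeds derive from the master seed hashed with the
(model, family) pair), and the held-out family's log predictive density is

    lpd_i = log ( mean over draws of exp Σ_dyads pattern_loglik(y_d | θ_d = x_d'b) )

with the unseen family's random intercept at its prior mean 0 (a config
option integrates over Normal(0, τ) by Monte Carlo instead). Held-out
families with whole-scale-missing continuous predictors get those entries
replaced per draw by the conditional mean of the fitted multivariate
normal given their observed entries. Families with no observed outcome
items at all are excluded from scoring (they carry no predictive
information) but kept in every training set; the manifest records them.

Model comparison reports each model's ELPD difference to the best model and
the standard error sqrt(F · Var(pointwise differences)). Stacking weights
maximize Σ_i log Σ_k w_k exp(lpd_ik) over the simplex — a concave problem
solved by SLSQP from the uniform start (exact ties therefore stay uniform
on the tied set), with a vertex check guarding solver early stopping.

## The synthetic-data generator

The generator is the study-design emulator that makes every downstream
stage testable. Defaults are the emulated study conditions: 60 families;
P(two parents) = 40/60, P(mother only) = 17/60 (expected 43 fathers, 57
mothers); adolescent age uniform 13–17, 55/60 female; true predictor
scores from a multivariate normal with the reported correlation structure
(e.g. depression–elevation 0.58, agency–elevation −0.54); standardized
effects agency 0.2, communion 0, elevation 0.1, paternal depression −0.16
with maternal interaction +0.16; τ = 0.46, σ = 0.52, ν = 20. Item-level
missingness is MCAR at 0.7% (CBQ), 0.4% (IIP-C), 0.1% (SCL); whole-scale
dropouts default to 2 CBQ, 3 SCL, 1 IIP-C, with the IIP-C dropout
coinciding with an SCL dropout.

Conflict items come from a 2PL bank drawn from the model's own priors:
discriminations from the truncated Gamma(2, 0.5), difficulties N(0, s) with
s itself drawn half-t(3,0,1) per bank. Because s is heavy-tailed, occasional
banks are nearly uninformative (all difficulties equal, or spread far beyond
the θ range); such prior-predictive replicates are kept deliberately — they
are exactly the regime in which the soft scale identification drifts, and
recovery statistics are therefore evaluated across replications, not per
seed.

Ordinal questionnaire items are built from linear propensities around the
true scores (octant propensity elevation + agency·sin + communion·cos for
the IIP-C; the depression score for the SCL), plus item noise, discretized
by rounding to the legal range — the simplest controllable ordinal
mechanism; no claim is made that real IIP-C item distributions look like
this. What passing recovery tests show is that the estimator recovers
effects under the declared generative process at the study's size; they
cannot show robustness to measurement structures the generator does not
produce (ordinal asymmetries, non-MCAR missingness, informative dropouts).

## Problem sizes used by tests and the acceptance script

Parameter recovery runs 10 replications at 60 families (~100 parents, 2
chains × 500/500); the robustness-limit check compares a ν = 10⁶ t fit with
a normal fit on one such dataset; the conjugate leave-one-out oracle uses 8
single-dyad families at 4000 draws; the end-to-end CLI run uses 10 families
with 2 chains × 200/200 and exact LOO over all four models; the acceptance
script fits M2 and M3 at 60 families and runs the four-model exact LOO on a
10-family subset (2 × 250/250 per refit). These sizes are the package's
test profile; the library defaults remain the full study-scale settings.

## Known limitations

- The latent scale is only softly identified without the θ anchor;
  variance-parameter posteriors (σ², τ²) can sit above their generating
  values for weakly informative item banks, inflating coefficients by the
  same factor. The anchor option trades this for deterministic shrinkage.
- Exact LOO is expensive by construction (families × models refits); there
  is deliberately no importance-sampling approximation.
- The two-way imputation is the single-pass estimator; it is not the
  additive-ANOVA EM fit (see above).
- Norm tables for octant standardization are external inputs; the bundled
  synthetic table only reproduces the generator's marginals.
- The stability diagnostic treats the two-way residual SD as the imputation
  noise scale; it does not propagate uncertainty in the person/item means.
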