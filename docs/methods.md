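# Methods

`pedgibbs` implements a Bayesian quantitative-genetic analysis of juvenile
survival in a small, pedigreed captive population: which part of the
variation in whether a calf survives its first month is attributable to the
calf's own genes, to its mother's genes acting as the calf's environment,
and to non-genetic conditions the mother provides to all her offspring.

## The model

A calf record is modelled as

```
y = Xb + Zu + Mm + Wc + e
```

* `y` — survival records, one per calf. On the *continuous* scale the 0/1
  outcome is treated directly as a Gaussian response; on the *threshold*
  scale it is the indicator `1[l > 0]` of a latent Gaussian liability `l`
  with residual variance fixed at 1 and threshold at 0.
* `b` — systematic effects with flat priors: calving year (sparse years
  pooled to a minimum of 5 records per level), dam parity (primiparous /
  multiparous), dam age at calving in days as centered linear + quadratic
  covariates, and the 6-level litter composition F, M, F(F), F(M), M(F),
  M(M) (own sex; cotwin's sex in parentheses). Optional inbreeding
  covariates: mode I none, mode II the calf's inbreeding coefficient F as
  linear + quadratic, mode III the individual increase in inbreeding dF as
  linear.
* `u` — direct additive genetic effects of all pedigree members, prior
  `N(0, sigma2_u A)` with `A` the numerator relationship matrix.
* `m` — maternal genetic effects (the dam's genes as offspring
  environment), prior `N(0, sigma2_m A)`, sampled jointly with `u` through
  a 2x2 covariance `G` when both blocks are in the model.
* `c` — maternal permanent-environment effects, one iid level per dam with
  at least one record, `N(0, sigma2_c I)`.
* `e` — residuals, `N(0, sigma2_e I)`; `sigma2_e = 1` under the threshold
  scale.

Four fittable variants: **Calf** (u only), **Calf-dam** (u, m),
**Calf-permanent** (u, c), **Calf-dam-permanent** (u, m, c), each on either
scale. The full model with a paternal genetic block fitted jointly with all
of the above is not estimable (more covariance parameters than the
relationship structure can separate); the design layer can build its
incidence, but the sampler refuses to fit it.

Identifiability of `X` uses reference-level coding (the first observed
level of each factor is absorbed), matching how results are reported as
level contrasts. Covariates are centered at their sample means; a covariate
that is constant after centering (e.g. dF in a fully outbred data set) is
dropped as confounded with the intercept.

## Pedigree quantities

* **F** — inbreeding coefficients by the Meuwissen & Luo ancestor-walk
  algorithm; exactly equal (to 1e-12, tested) to the tabular-method
  diagonal `A_ii - 1`.
* **t** — equivalent complete generations, the recursion
  `t_i = sum over known parents (1 + t_parent)/2`.
* **dF** — individual increase in inbreeding,
  `dF = 1 - (1 - F)^(1/(t-1))` for `t > 1`; defined as 0 for `t <= 1`
  (a founder or near-founder has no pedigree depth over which to
  accumulate inbreeding — the edge case is a package decision).
* **A** — tabular method, intended as a small-scale oracle (guarded at
  4,000 individuals).
* **A⁻¹** — Henderson/Quaas sparse rules with full inbreeding
  accounting; round-trips against the tabular `A` to better than 1e-8 on
  test pedigrees.

Unknown parents are phantom founders: unrelated and non-inbred; no
genetic-group modelling.

## Priors: why they are scale-appropriate

The classical weakly-informative choice for variance components in this
literature, a scaled inverse-chi-squared with small df and **zero scale**,
has density `(sigma2)^-(v/2+1)` that is non-integrable at zero. Whenever
an effect vector can shrink to zero — the permanent-environment block
competing with the maternal genetic block is the canonical case, the two
sharing identical incidence for every dam — the joint posterior is then
improper, with infinite mass at `sigma2 = 0`; its inverse-Wishart
analogue piles infinite mass onto rank-1 `G` (direct-maternal correlation
pinned at +-1, heritability crushed). Both collapses were reproduced with
two independent implementations (the production kernel and a dense
numpy/scipy reference with jointly sampled location effects), on weakly
and strongly informative data, confirming they are properties of the
prior rather than of the code.

The package therefore defaults to:

* **Continuous scale: flat (constant-density) priors on all variances** —
  the common default in animal-model Gibbs software — giving the
  zero-repelling conditionals `sigma2 = SS / chi2_{q-2}` (scalar,
  including the residual, whose conjugate intercept-only posterior is
  then scaled-inv-chi-squared with `nu = n - 3`) and
  `G ~ InvWishart(S_q, N-3)` (2x2).
* **Threshold scale: a bounded-uniform prior on the systematic effects
  and informative proper priors on the effect variances** (df 20, scale
  0.1 on the unit-residual liability scale, prior mean ~0.11; the
  residual is fixed at 1). Two separate escape channels exist for binary
  data. A completely separated level of a flat-prior factor (e.g. a
  pooled calving year in which every calf survived — the real studbook
  had such years) walks to infinity on the liability scale; the bounded
  prior (half-width 8 liability units, inert otherwise) stops it. More
  fundamentally, with one record per animal the per-record breeding
  values can separate the outcomes, so the marginal likelihood *rises
  gently* toward arbitrarily large genetic variance and the posterior
  scale of the threshold model's variance components is determined
  largely by the prior. The informative default states that expectation
  explicitly; threshold-scale variance ratios should accordingly be read
  as prior-informed summaries, not data-driven estimates, and the
  continuous scale preferred for variance-ratio inference (consistent
  with the predictive-ability comparison, which favours continuous
  models).

All prior settings (df and scale per component family) are
config-overridable (`GibbsConfig.prior_df`, `effect_var_prior_df`,
`effect_var_prior_scale`, `genetic_matrix_prior_df`,
`genetic_matrix_prior_scale`).

On the observed (continuous) scale the bounded-uniform prior on `b` uses
half-width 1e6, which is never active; draws are then plain Gaussian.

## Sampler

Gibbs sampling with the following update structure per iteration:

1. **Liabilities** (threshold scale): each record's latent liability from
   a truncated normal — simple rejection for truncation points below 0.45,
   Robert's exponential rejection deeper in the tail, robust beyond
   |predictor| = 8 (tested).
2. **Location effects**: systematic and permanent-environment effects by
   single-site scalar draws from their Gaussian full conditionals. The
   genetic effects of each pedigree member are drawn as a joint `(u_i,
   m_i)` bivariate-normal block when both genetic effects are fitted:
   their data cross-product is exactly zero (no record has the same
   individual as both calf and dam), so the 2x2 conditional costs no more
   than two scalar draws, and it removes an absorbing state in which a
   sampled genetic correlation near +-1 locks `u` proportional to `m`.
   When the permanent-environment block is also present, each
   `(m_dam, c_dam)` pair — whose incidence is identical — is additionally
   drawn jointly in a second pass, which transfers variance directly
   between the two competing dam-level effects.
3. **Variance components** from their conditionals as above, with a
   1e-10 floor against numerical underflow, up to 10 redraws of a
   numerically non-positive-definite `G`, and a hard cap
   `|r_g| <= 0.999` on the sampled genetic correlation (a correlation
   within rounding error of +-1 makes the pair-conditional precision
   catastrophically ill-conditioned).

The residual vector is maintained incrementally and recomputed from
scratch every `residual_check_every` iterations (default 10,000); the
worst drift observed is reported in the chain metadata (order 1e-13 in
tests, tolerance 1e-8).

Default chain settings are 1,000,000 iterations, 100,000 burn-in,
thinning 100. Tests, cross-validation refits and the acceptance runs use
reduced chains (typically 8,000–24,000 iterations with 2,000–6,000
burn-in and thinning 10), sized so that the full test suite and the
acceptance script each run on a single CPU at desk scale; segment-wise
stability and effective sample sizes of the reduced chains were checked
when the sizes were chosen. Chains are bit-reproducible given seed and
config (numba's own RNG, seeded once per chain). Effective sample size
and a Geweke-style z are reported as advisory output only; no formal
convergence criterion is applied.

## Posterior summaries

Ratios are computed per saved sample and then averaged:
`h2 = sigma2_u / sigma2_P`, `m2 = sigma2_m / sigma2_P`,
`c2 = sigma2_c / sigma2_P`, `r_g = sigma_um / sqrt(sigma2_u sigma2_m)`
with `sigma2_P = sigma2_u + sigma2_m + sigma2_c + sigma2_e`. The
direct-maternal covariance is **excluded** from `sigma2_P` so the shares
stay in [0, 1]; a switch adds it for sensitivity. Contrast probabilities
are posterior fractions `P(effect_a - effect_b > 0)`; level-wise survival
estimates are the population-average systematic predictor with the level's
effect swapped in — probit-transformed on the threshold scale, clipped to
[0, 1] for reporting (never for inference) on the continuous scale.
Dam-age response curves report the posterior of the quadratic profile and
the optimum `x* = x_mean - b_lin / (2 b_quad)` per sample, flagged
unreliable when more than half the posterior mass has a non-negative
quadratic coefficient. Genetic trends are per-sample cohort means of
breeding values by birth year, summarized as posterior means and
`P(cohort mean > 0)`.

## Cross-validation

The reference population is every record in the 5 most recent calendar
years containing at least one record; half of it (floor on odd sizes) is
withheld uniformly at random, the model refit on the remainder (the
withheld calves stay in the pedigree, so their breeding values are
propagated through relatives), and the withheld records predicted by the
posterior-mean linear predictor — observed scale for continuous models,
liability scale for threshold models. The Pearson (point-biserial, for
binary truth) correlation is averaged over 20 replicates. Replicate split
seeds are shared across model variants so comparisons are paired; a
replicate with constant withheld outcomes or predictions has no defined
correlation and is excluded from the mean with a warning. Year levels
present only in a test set are mapped to the nearest pooled training
level; a test dam without a training permanent-environment level
contributes its prior mean, zero.

## Synthetic studbooks

The generator emulates the captive program's structure: founding from 1
male and 3 females; harem herds of one adult male and 5–8 adult females,
the male rotated so he never serves the same herd in consecutive seasons
(with an emergency fallback that keeps the youngest over-age male
breeding rather than losing the line); females fertile from the next
season; twin calvings with probability 0.39; baseline survival 0.79 on
the liability scale (intercept scaled by the total liability SD and
shifted for the mean litter/parity penalty so the marginal frequency
lands near the target). Breeding values `(u_i, m_i)` follow the
Mendelian-sampling recursion with the exact parental inbreeding
coefficients, so realized variances, the mid-parent regression slope of
1, and inbreeding accumulation from the bottleneck all emerge correctly
(tested). Systematic-effect magnitudes (male penalty, twin penalty,
male-cotwin penalty, primiparous penalty, dam-age optimum near 9 years)
mirror the qualitative pattern reported for this population with
package-chosen magnitudes.

The `paperlike` preset reproduces the real studbook's reported scale within
±15%: ~740 animals, ~700 records, ~196 distinct dams, ~60% of records
twin-born, ~79% survival. `tiny` runs the full pipeline in seconds.
`selected` applies truncation selection on true direct breeding values at
recruitment; `selectionless` is its random-mating control. Two further
configurations define the main simulation studies: `recovery_sim_config`
(~2,000 continuous records, true h2 = 0.30, m2 = 0.15, c2 = 0.15, zero
direct-maternal covariance, a broader founder base of 8 males + 40
females, and dam careers of ~5 calvings so the within-dam replication can
separate `m` from `c`) and `maternal_sim_config` (strong maternal genetic
component, m2 = 0.35 vs h2 = 0.15, for predictive model discrimination).

What the generator does **not** emulate: real husbandry interventions
(removals, transfers between institutions), mortality causes, seasonal
structure within years, and any environmental trend; passing tests on
synthetic data therefore show the machinery is correct under the model's
own assumptions, not that the model is adequate for any particular real
studbook.

## Known limitations

* The direct-maternal genetic correlation is very weakly identified at
  these data scales (the posterior SD is large on any single data set);
  its estimates should be read as exploratory, and the variance-share
  summaries are the robust output.
* Separating `m2` from `c2` requires dams with several offspring and
  related dams; with short dam careers the posterior will lean on one of
  the two, as the recovery experiments show.
* Continuous-scale analyses of a 0/1 trait are a linear approximation;
  the threshold scale is the generative reading, but its chains mix more
  slowly and its predictive correlations are computed on the liability
  scale.
* REML/BLUP estimation, multi-trait models, genomic relationship matrices
  and formal convergence diagnostics are out of scope.
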