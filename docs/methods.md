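# Methods

## The model

`occaban` analyses multi-species presence/absence surveys collected under a
nested spatial design — survey plots inside settlements inside climatic
regions — where each settlement is either inhabited or abandoned.  The core
model (variant **M1**) is a random-slope logistic GLMM.  For species *i* at
plot *j*:

    Y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = beta0_i + beta1_i*ABAN_j + beta2_i*TEMP_j + beta3_i*MONTH_j
                  + beta4_i*I(LU_j = dry field) + beta5_i*I(LU_j = built-up)
                  + eps_reg(j) + eps_set(j) + eps_lu(j)

`ABAN_j` is either the binary "abandoned or not" indicator or the years
since abandonment (0 for inhabited settlements); `TEMP_j` is the mean annual
temperature of the plot's region; month and land use (paddy field is the
baseline category) are confounders.  The group effects are independent
normals: `eps_reg ~ N(0, sigma_r^2)` per region, `eps_set ~ N(0, sigma_s^2)`
per settlement and `eps_lu ~ N(0, sigma_l^2)` per settlement-by-land-use
combination (plots of one land-use type cluster spatially within a
settlement, so the land-use random effect is nested in settlements).

The abandonment and temperature slopes are drawn jointly across species:

    (beta1_i, beta2_i) ~ MVN((mu_b1, mu_b2), Sigma)
    Sigma = [[s1^2, rho*s1*s2], [rho*s1*s2, s2^2]]

`rho` is the focal quantity of variant M1: a positive value means species
with colder thermal niches respond more negatively to abandonment.  The
confounder slopes beta3..beta5 get independent normal priors with free means
and SDs.

Variant **M2** replaces the shared slope means with a one-habitat hierarchy,
`mu_b1i = alpha0 + alpha1*H_ik` (and `mu_b2i = alphaT0 + alphaT1*H_ik`),
where `H_ik` indicates whether species *i* uses habitat type *k*; it is
fitted separately for each of the 11 habitat types.  Variant **M3** uses all
11 types at once, `mu_b1i = alpha0 + sum_k alpha_k*H_ik`, with ridge
shrinkage implemented as `alpha_k ~ N(0, tau^2)` and a half-Cauchy(5)
hyperprior on the shared scale `tau`; hierarchical `tau` avoids hand-tuning
a ridge penalty.  By default the temperature coefficient block is shrunk the
same way (`PriorConfig.ridge_temperature=False` reverts the temperature
slope means to a single free mean).

Priors: `beta0_i` and free slope means `~ N(0, 100)`; M2/M3 alphas
`~ N(0, 1000)`; every SD `~ half-Cauchy(5)` (this includes `sigma_l`, which
is treated like the other two group scales); `rho ~ Uniform(-1, 1)`.

## Sampling

The posterior is explored with a No-U-Turn sampler written for this package
(`occaban.nuts`): multinomial trajectory sampling with biased progressive
weights, dual-averaging step-size adaptation (target acceptance 0.8),
diagonal mass-matrix estimation over expanding warmup windows, divergence
detection at an energy error of 1000, and a maximum tree depth of 10.  All
random effects and species slopes use a non-centered parameterization, scales
are log-transformed and `rho` is tanh-transformed (with Jacobians), and the
likelihood gradient is computed analytically, which keeps desk-scale fits in
seconds to a couple of minutes.  Defaults follow the standard protocol for
this analysis: 3 chains, 1000 warmup + 1000 sampling iterations, no
thinning (3000 draws).  Convergence is judged by rank-normalized split
R-hat with the conventional 1.1 threshold; non-convergence warns and flags
the result rather than raising, because reduced desk-scale runs can be
marginal.  `rho` is clamped to |rho| <= 1 - 1e-12 after the tanh transform
so the bivariate normal stays proper at the numerical boundary.

Equal-tailed quantile intervals are used for all credible intervals; a
species is called a significant "loser" when the upper bound of the 95%
interval of its abandonment coefficient is below zero (and a "winner"
symmetrically).

## Model comparison

The two abandonment codings are compared by WBIC: draws are taken from the
tempered posterior `prior x likelihood^(1/log n)` and WBIC is the posterior
mean of the untempered negative log-likelihood.  `n` is the number of
Bernoulli records (species x plots), the standard convention when the
likelihood factorizes over records; it is configurable because the exponent
depends on it.  The Bayes factor of coding A over B is `exp(WBIC_B -
WBIC_A)`; the lower-WBIC coding is selected.  WBIC of a model whose
likelihood is identically one is exactly zero, and on a conjugate
normal-mean toy the implementation is checked against the closed-form
marginal likelihood.

## Posterior predictive checking

Five community-level statistics: overall presence proportion, the same
proportion restricted to abandoned and to inhabited settlements, the Gini
coefficient of per-settlement presence proportions, and the Gini coefficient
of per-species presence proportions.  Settlement proportions are unweighted
by plot count (a settlement's proportion is presences / (species x its
plots)); plot-count weighting is available behind the ``weight_by_plots``
flag.  The Gini coefficient is the pairwise form
`G = sum_ij |x_i - x_j| / (2 n^2 mean(x))`, computed via the sorted
O(n log n) identity.  Replicate data sets are simulated per posterior draw
conditioning on that draw's group effects (the ``redraw_group_effects``
option re-draws them from N(0, sigma^2), giving a mixed predictive check
instead).  The p-value is the upper-tail
frequency with half weight on ties; values outside (0.025, 0.975) are
flagged as significant divergence.

## Projection (CL/CG)

The ridge model predicts an abandonment response `mu_b1i` for any species
from its habitat vector — including species never observed in the survey.
For each grid cell of a range stack, cumulative loss CL is the sum of
|effect| over present species with negative effects, and cumulative gain CG
is the sum over positive effects; effects stay on the logit scale (the
coefficients are summed directly, no probability transformation).  Sums are
formed per posterior draw and then summarized, so the SD maps are true
posterior SDs of CL and CG (`per_draw=False` gives the point-estimate
variant from posterior-mean effects).  Proportions `CL/(CL+CG)` are
undefined (flagged, not zeroed) in cells with no present species or
all-zero effects.  Red-list maps are the same computation on the flagged
species subset; CL is additive over disjoint species subsets by
construction.

## Synthetic data

The generator reproduces the hierarchical sampling design the models were
built for: 18 regions with mean annual temperatures evenly spaced over
4.5-15.7 degC (one MAT per region, optional jitter, default 0), 2-5
settlements per region with roughly 53% abandoned (at least one of each
type per region when possible), abandonment assigned at settlement level,
years since abandonment uniform on 8-53 for abandoned settlements, 4-16
plots per settlement spread over the three land-use types, one survey month
(May-August) per settlement, and 49 species by default.  Occupancy is drawn
from model M1 itself on the standardized covariate scale (the scale the
model is fitted on).  Default generative hyperparameters are free choices
documented here, not estimates: slope means (-0.5, 0.5, 0, 0, 0), slope SDs
(1, 1, 0.3, 0.3, 0.3), rho = 0.4, group SDs (0.5, 0.5, 0.5), intercepts
N(-2, 1) giving realistically sparse occurrence (~15-20% presence).
Habitat-preference vectors draw 1 + Poisson(1.5) of the 11 types per
species; the range-stack generator is independent Bernoulli per cell and
species at a configurable prevalence (no spatial autocorrelation) and
stands in for model-projected range maps.

What the generator does *not* emulate: detection error (the model treats
raw presence/absence as truth), phenology beyond the month covariate,
spatially structured climate within regions, spatial autocorrelation in
ranges, and correlations between habitat preference and range size.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation.

## Verification experiments and their sizes

All checks run on synthetic data at reduced sizes chosen so the full suite
runs on one CPU in well under half an hour:

- M1 recovery: 10 regions, 20 species, ~300 plots, 2 chains x (300 warmup
  + 300 draws), true rho = 0.5.  Checks: all R-hat < 1.1; rho, mu_b1 and
  the three group SDs inside their 95% CIs.
- rho coverage: 6 replicate data sets (8 regions, 15 species), >= 5 of 6
  intervals must cover (the binomial tolerance matching a 95% interval at
  this replicate count).
- M2: 24 species, half grassland / half forest, true grassland contrast
  alpha1 = -1; the posterior must be negative with 95% CI excluding zero.
- Coding selection: 4 replicates per direction at 10 regions / 16 species
  with a -2.0 step (or the equivalent linear-in-years slope), tight slope
  heterogeneity (SD 0.3) and small group SDs (0.2): at smaller sizes the
  two codings are genuinely indistinguishable because settlement random
  effects absorb the misfit of the wrong coding.  >= 3 of 4 correct
  selections per direction.
- PPC calibration: 4 replicates fitted with the generating model; all five
  p-values must lie in (0.025, 0.975) in >= 3 of 4.
- WBIC validity: conjugate normal-mean toy (n = 100) against the analytic
  marginal likelihood, 5 sampler seeds, < 5% relative error.
- Exact oracles: likelihood and linear predictor against term-by-term
  sums (1e-12), Gini against the O(n^2) double sum (1e-12), CL/CG against
  a triple loop (1e-10), analytic gradients against finite differences.

`scripts/acceptance.py` re-runs the main computation end-to-end (M1 fit,
coding comparison, PPC, M3 + projection on a 400-cell synthetic stack) at
the M1-recovery size above and writes every headline quantity to JSON.

## Known limitations

- The sampler is single-threaded pure NumPy; full-size runs (49 species,
  ~3800 plots, 3x2000 iterations) take tens of minutes, not seconds.
- WBIC values from short tempered chains carry Monte-Carlo noise of a few
  units; model comparisons should rely on gaps well above that, or longer
  chains.
- M2 is fitted once per habitat type (11 separate fits for a full
  analysis), as the hierarchy is defined per type.
- The habitat-based prediction transfers to unsurveyed species only insofar
  as habitat preference captures their abandonment response; generalist
  species with many habitat types get averaged predictions with wide
  uncertainty.
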