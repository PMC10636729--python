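# Methods

## Model and likelihood

Each observation is a trait value `y` on a unit (an individual for
offspring traits, a single trial for repeated FID measures), modelled as

```
y = x'b + u_mother + a_individual + e
```

Gaussian traits have Gaussian residuals; the binary survival trait is
modelled on a latent logit liability: the liability `l` carries the linear
predictor plus a residual with variance fixed at 1, and the observed
outcome is Bernoulli(logistic(l)). Mother-level effect vectors across all
traits are multivariate normal with an unstructured covariance matrix `G`,
so `G` houses each trait's mother-level variance and every cross-trait
mother-level covariance (including, for the bivariate FID model, the
mother–offspring covariance that feeds the upper-limit heritability).
Individual-level effects (offspring identity in the repeated-measures FID
model) are univariate normal per trait.

Residual covariance is defined per *unit*: traits sharing a unit (the three
offspring traits in the four-trait model) have a free residual covariance
block, while traits on disjoint unit sets (offspring traits versus adult
female FID) have their residual covariance fixed to exactly zero. The
zero-mask partitions the residual matrix into independent blocks, each with
its own inverse-Wishart update.

## Priors

* Fixed effects: improper flat priors.
* Each covariance block (mother-level `G`, individual variances, residual
  blocks): inverse-Wishart with scale `V = I` and degrees of freedom
  `nu = dim + 0.002`. This is proper and weakly informative; in one
  dimension it is a scaled inverse-chi-square barely tighter than the
  boundary of propriety. The source analysis states only that an
  inverse-Wishart prior was used, without hyperparameters; these defaults
  are the package's own choice and are configurable through
  `ModelSpec.priors`.
* The residual block containing the binary trait has its diagonal element
  fixed at 1. Its prior (and conditional posterior) is the inverse-Wishart
  *conditioned* on that element. Draws use the partition property of the
  inverse-Wishart — the Schur complement and the regression coefficients of
  the free block are independent of the fixed sub-block — verified in the
  test suite against a rejection sampler.

## Sampler

A blocked Gibbs sweep per iteration:

1. latent liabilities (and any augmented missing responses) given
   everything else — single-site Metropolis with a Gaussian random walk
   whose scale adapts toward 44% acceptance during burn-in only, so the
   retained chain satisfies detailed balance;
2. all fixed effects jointly by a generalized-least-squares draw;
3. mother-level effect vectors, vectorised across mothers;
4. individual-level effects;
5. `G`, individual variances and residual blocks by (conditional)
   inverse-Wishart draws.

Missing responses inside a multi-trait residual block are integrated out by
per-iteration augmentation, which leaves the posterior of all parameters
identical to omitting those likelihood contributions. Augmentation needs
the cell's linear predictor: rows present in the table with an empty value
supply their covariates; units lacking a row for a block trait entirely are
augmented at reference covariate levels (numeric covariates centred,
factors at baseline), a mild approximation documented here because no
covariates exist for such cells.

One `numpy` Generator seeded from `MCMCConfig.seed` drives every draw, so
fits are bit-reproducible. Posterior correctness is checked three ways in
the tests: against a brute-force grid-integration posterior on a 3-mother
toy (total variation < 0.05 with 50 000 retained samples), against
method-of-moments ANOVA estimates on balanced designs, and by
HPD-coverage calibration over 20 replicate simulations at the study's
design scale.

Default chain settings (20 000 iterations, 5 000 burn-in, thinning 10) are
test-scale choices that mix adequately for the design sizes the generator
emulates; the original analysis's 1.3 million-iteration settings are
available through `MCMCConfig`. Effective sample sizes (autocorrelation
based, via arviz) below 200 trigger warnings that are propagated into the
analysis report.

## Scale conversion for the binary trait

Latent-scale components of survival convert to the observed 0/1 scale by
Gauss–Hermite quadrature: with `p(l) = logistic(l)` and liability
`l = mu + m + e`, the expected phenotype is `pbar = E[p]`, the data-scale
mother-level variance is `Var_m(E[p | m])`, the binomial sampling variance
is `E[p(1-p)]`, and the data-scale residual is the remainder of the
Bernoulli total `pbar(1-pbar)` (law of total variance). Data-scale maternal
repeatability divides the mother component by that total. The conversion is
applied per posterior sample with the sample's fixed-effect predictors as
the `mu` vector (an intercept-only mode exists), and is cross-validated
against a brute-force Monte Carlo estimator with calibrated standard
errors. Only the logit link is implemented.

A note on the printed decomposition being emulated: the published
data-scale formula divides by latent `var_Residual = 1` alongside
data-scale terms, i.e. it mixes scales as printed. This package computes
the fully data-scale decomposition, whose three components provably sum to
`pbar(1-pbar)`; the qualitative conclusion — a large latent-scale maternal
repeatability collapsing severalfold on the data scale — is reproduced, but
exact data-scale percentages from the mixed-scale formula are not targeted.

## Posterior summaries

Variance parameters and derived ratios are summarised by the mode of a
Gaussian KDE on a 2 048-point grid. The bandwidth is Silverman's robust
rule of thumb `0.9 min(sd, IQR/1.34) n^(-1/5)` multiplied by 0.7: the rule
of thumb targets global density accuracy, and its smoothing bias visibly
shifts the peak of the right-skewed posteriors summarised here, while mode
location tolerates the small extra variance of a narrower kernel. HPD
intervals are the shortest contiguous window containing `ceil(0.95 N)`
sorted samples. pMCMC is twice the smaller tail fraction, floored at `1/N`
because a finite chain cannot certify an exact zero. All ratios (Eqs for
repeatability and heritability) are computed per retained sample and then
summarised — never as ratios of point summaries; the small worked examples
in the tests that use point ratios are fixed test vectors, not the pipeline
path.

## Synthetic data

The generator reproduces the study's design: 156 adult females with 1–14
FID trials (mean 5.6), 111 of them with 1–3 offspring (truncated Poisson,
mean 1.6); survival scored for every offspring with a latent intercept of
1.0 giving ~67% survival; PY movement scored for ~70% of offspring as the
fraction of 8 handling stages with movement (each stage an independent
Bernoulli draw from a shared per-individual logit propensity; a 6-stage
protocol variant is configurable); subadult FID measured for ~59% with
1–10 trials (mean 4.6). Mother-level effects are drawn from a configurable
4×4 covariance whose defaults sit at the scale of the published estimates
(FID variances near 5 m², their covariance 4.14 m², survival latent
variance 1.54). Covariate distributions (sex Bernoulli(0.5), year uniform,
group size uniform on 1–6, companion-class frequencies at the published
percentages, east–west coordinate uniform on a 4 km interval, first-test
sentinel of 500 days) are emulation choices documented in
`SimulationConfig` defaults.

What the generator does not emulate: spatial structure beyond the linear
east–west coordinate, behavioural mechanisms of habituation (a linear test
number effect only), age-structured survival, non-Gaussian FID residuals
(FID is Gaussian by default, matching the fitted family; truncation at zero
is available but off). Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to the ways real field data violate them.

## Numerical choices and degenerate inputs

* Design matrices: intercept plus centred numeric covariates and
  baseline-dropped factor dummies (sex baseline male, year baseline 2017,
  companion class baseline "alone"); rank-deficient designs are rejected.
* A dataset in which every mother has a single observation triggers a
  weak-identifiability warning, not an error.
* Inverse-Wishart draws use a Bartlett factorisation and require
  `nu > dim - 1`.
* Samples with non-positive mother-level variance are excluded (with a
  count warning) from the per-sample heritability ratio.
* The adoption regression uses per-animal mean FIDs and ordinary least
  squares: with a handful of cross-fostering cases, hierarchical estimation
  is foreclosed, and the wide confidence intervals are the honest output.

## Known limitations

* No pedigree/animal-model relatedness: mother-level variance conflates
  additive-genetic and maternal-environment effects by design, which is why
  the heritability is only an upper bound.
* Single chain; convergence diagnostics are ESS-based warnings rather than
  multi-chain R-hat.
* Binary traits are two-level only; the probit link and multi-category
  traits are out of scope.
* Units absent from the table entirely are augmented at reference covariate
  levels (see Sampler above).
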