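# Methods

This note documents the statistical choices inside `ersmix`: what each
engine assumes, the tunable parameters that matter, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
shared across modules.

## Data model and shared preprocessing

All engines work on log10-transformed exposures and outcome (skewed,
strictly positive concentrations; base 10 so one unit means a ten-fold
concentration change). The transform is applied once and guarded against
double application. Values below an assay's limit of detection are
substituted by LOD/√2 *before* the transform, mirroring the usual
biomonitoring substitution-then-analysis order; no alternative LOD
imputation is implemented.

Covariates are encoded by reference-cell indicators (first observed level
is the reference). Exposure main effects are standardized to training-set
mean 0 / SD 1 before interaction products are formed, making the penalty
scale-equivariant; the outcome is left unstandardized. Test-set columns
always reuse training-set means/SDs. Whether to standardize before
penalization is a genuine open choice — we standardize because it is
standard practice for penalized regression, not because the method
requires it.

Two engines (sum-of-trees, super learner) operate on residualized data:
ordinary least-squares residuals of the outcome and of each exposure on
the covariate design. The projection coefficients are stored so held-out
data are residualized with training-set fits. The other two engines
(adaptive elastic net, kernel machine) carry the covariates inside the
model unpenalized/parametrically. This asymmetric treatment of covariates
is a property of the workflow being implemented, not a recommendation;
it assumes covariates act linearly and ignores exposure-by-covariate
interactions.

The train/test split is a seeded permutation split, default ratio 0.5.

## Adaptive elastic net (AENET-M / AENET-I)

Objective: RSS + λ₁ Σ ωⱼ fⱼ |βⱼ| + λ₂ Σ fⱼ βⱼ², solved by cyclic
coordinate descent on the Gram form with warm starts along the λ₁ path.
Penalty factors fⱼ are 0 for covariates (never shrunk) and 1 for exposure
terms. The objective is asserted non-increasing every sweep; convergence
is max coefficient change < 1e−9 (1e−8 inside CV paths).

Stage 1 tunes (λ₁, λ₂) by K-fold CV (default K = 5) over a 50-point λ₁
path spanning four decades down from λ₁_max (the smallest λ₁ nulling all
penalized terms, computed after projecting out the unpenalized columns)
and λ₂ ∈ {0, 1e−4, 1e−3, 1e−2, 1e−1}·n. Stage 2 sets adaptive weights
ωⱼ = (|β̂ⱼ| + 1/n)^(−γ), γ = 1 (the 1/n ridge keeps weights finite at
exact zeros), re-tunes λ₁ with λ₂ carried over, and rescales the
penalized coefficients by (1 + λ₂/n) to undo compound ridge shrinkage.
The rescale is applied to penalized terms only: covariates are not
ridge-shrunk, so rescaling them would bias their estimates.

Two CV selection rules are available: minimum mean CV error (default,
best for prediction) and the 1-SE rule (largest λ₁ within one standard
error of the minimum, best for formal support recovery — minimum-CV
tuning of the lasso family is known to overselect). Ties resolve toward
larger λ₁ (sparser model). On the package's selection-consistency
benchmark (n = 2000, 55 candidate terms, 5 true), min-CV recovers all
true terms but averages ≈ 7 false positives; the 1-SE rule recovers all
true terms with ≈ 0 false positives.

SEs and p-values for selected terms use a sandwich covariance built on
the selected submodel's penalized information (X_A′X_A + λ₂ diag f),
treating the selection as fixed. These are approximate: post-selection
inference after data-driven variable selection is optimistic, and the
values should be read as descriptive.

The ERS is the weighted sum over selected exposure terms only —
covariates and the intercept contribute nothing, so the score isolates
the mixture signal.

## Bayesian sum-of-trees

Standard regularized sum-of-trees regression: m trees (default 200;
desk-scale tests use 20–50), outcome rescaled to [−0.5, 0.5]. Priors:
depth-d split probability 0.95·(1+d)^(−2); leaf values N(0, σ_μ²) with
σ_μ = 0.5/(k√m), k = 2; σ² a scaled inverse-χ² with ν = 3 calibrated so
the least-squares residual SD sits at the 90th prior percentile.

Each iteration updates every tree by one Metropolis–Hastings move against
its partial residual — grow (0.4), prune (0.4), change (0.2); no swap
move — with leaf values marginalized out of the acceptance ratio, then
draws leaf means conjugately and σ² from its conditional. Cut-point
candidates are midpoints of sorted unique values, capped at 100 per
variable. "Change" proposals are restricted to internal nodes whose
children are both leaves, and the uniform (variable, cut) proposal is
treated as canceling against the uniform rule prior; both are
simplifications of the classic sampler that affect posterior exactness
slightly but none of the package's accuracy checks (surface recovery,
importance ranking, σ calibration) detect any distortion.

Variable importance is the fraction of all split rules across retained
draws using each exposure (sums to 1). The ERS is the posterior mean
prediction at (residualized) exposures.

## Kernel machine regression

Y = h(E) + Z′β + ε with h ~ GP(0, λσ²K), K the Gaussian kernel with
per-exposure scales rⱼ ≥ 0 and inclusion indicators δⱼ. Sampling
marginalizes h (Y ~ N(Zβ, σ²(I + λK))), which mixes far better than
joint updates; h is recovered from its Gaussian conditional, and the
stored surface is the Rao-Blackwellized conditional mean per draw.

"Flat priors" are ambiguous for the variance-type parameters, so: β flat
(improper), σ² ~ inverse-gamma(0.001, 0.001), λ ~ Gamma(1, 0.1),
δⱼ ~ Bernoulli(0.5), rⱼ | δⱼ=1 ~ Exponential(1). Birth proposals draw
rⱼ from the slab (so the prior term cancels); active rⱼ alternate death
proposals with log-normal random-walk refinements (SD 0.5). Default
2000 iterations, burn-in 50%. PIPⱼ is the posterior frequency of δⱼ = 1.

Every iteration costs O(n³); above `max_exact_n` (default 1000) training
subjects the fit takes a seeded random subsample with a warning. The
full-cohort application size (thousands of subjects) is intentionally out
of desk scope.

The known failure mode of this engine — high training correlation with
near-zero held-out correlation when many correlated exposures are active
and h is flexible — is reproduced qualitatively by the test suite
(direction asserted, magnitudes not).

## Super learner

Default roster of seven base learners spanning the families commonly
stacked: constant mean, OLS, ridge, elastic net (this package's solver),
RBF kernel ridge, sum-of-trees (this package's sampler at reduced
settings), and gradient-boosted stumps. The registry is the extension
point: any object with deterministic fit/predict given a seed can be
added. Learners see residualized data only.

Level-1 predictions are strictly out-of-fold (V = 10 default); a learner
failing on any fold is dropped with a warning. Weights minimize
‖y − level1·a‖² over the simplex via non-negative least squares followed
by normalization — the standard practical solver; an exact SLSQP simplex
program is available (`exact=True`) and agrees with NNLS-normalize to
within grid-search resolution on the package's benchmarks. By simplex
feasibility the ensemble's CV loss never exceeds any single learner's.

Leave-one-exposure-out importance, (SSE(−j) − SSE)/SSE, uses the
cross-validated SSE (sum of squared out-of-fold ensemble residuals) and
reuses the baseline fold split for every rerun so the difference isolates
the omission. Negative values are possible and meaningful (omission can
help). Whether the original workflow computed in-sample or CV SSE is not
determinable; CV-SSE is chosen because it is the quantity the weights
optimize.

## Evaluation conventions

* **PRESS** here is the out-of-sample *sum* of squared prediction errors
  of `y ~ ERS + Z` (fitted on training, evaluated on test) — not the
  classical leave-one-out PRESS. MSPE is the same quantity divided by
  the test n; MSE is the training mean squared error.
* **AUC** is the rank (Mann–Whitney) statistic with ties averaged;
  verified against exhaustive pairwise comparison. CIs are 2000-resample
  bootstraps over test subjects. The permutation test permutes the ERS
  within the test set against fixed outcome/covariates and re-scores with
  the training-fitted logistic coefficients (no refit); p ∈
  [1/(n_perm+1), 1], n_perm default 1000.
* **Quintiles** use training-set cutpoints at the 20/40/60/80th
  percentiles (linear-interpolation quantiles everywhere in the package).
  The unadjusted Q5-vs-Q1 OR is the closed-form cross-product ratio with
  a Woolf CI — identical to the saturated logistic MLE without iteration
  error; the covariate-adjusted version is a logistic model with quintile
  indicators. With strong scores and rare outcomes the adjusted OR can be
  quasi-separated (empty case cells) and explode; this is the honest MLE
  on such tables. The end-to-end runner therefore degrades in order:
  adjusted OR → unadjusted cross-product OR → reported as unavailable
  (when an extreme quintile holds no cases at all), logging each step.
* **z-scoring**: ERS are standardized against the training distribution
  (sample SD, ddof = 1) so association estimates are per training SD.

## Association models

Linear and logistic endpoint models are unweighted maximum-likelihood
fits with Wald CIs (survey design — weights, strata, clusters — is out of
scope; this is the one systematic deviation from the survey-based
workflow the package mirrors). Mortality uses Cox partial likelihood with
attained age as the time axis: a subject is at risk at age t iff
entry < t ≤ exit, i.e. left truncation at study entry. Ties are handled
by Efron's method; the Newton tolerance is tightened to 1e−12 so the fit
matches a brute-force partial-likelihood maximization to oracle accuracy.
Age enters mortality models only through the time scale; other endpoints
adjust for age as a covariate.

## Synthetic cohorts

The generator draws a latent Gaussian with block-diagonal equicorrelation
(non-positive-definite blocks rejected by name), maps it to log-normal
concentrations via per-exposure geometric means/SDs, censors the lowest
`lod_quantile` fraction at LOD/√2, and builds log10(outcome) as
intercept + sparse main effects + sparse pairwise interactions (on the
centered log10 concentration scale) + covariate effects + N(0, noise_sd).
The binary endpoint dichotomizes a noisy liability sharing the latent
exposure score at the configured quantile (default 0.9); survival times
are exponential with the hazard scaled by the standardized score,
delayed entry at the subject's (age-distributed) enrollment age, and
uniform administrative censoring at 2–7 years of follow-up.

Defaults emulate a 20-biomarker metal panel from US biomonitoring data:
the published geometric means/SDs of the 20 metals, correlation blocks
matching the empirical Spearman structure (arsenic-species cluster at
0.65, broad urinary-metal cluster at 0.45, blood lead–cadmium at 0.35),
true effects equal to published mixture-regression coefficients for an
oxidative-stress marker (blood lead 0.31, urinary cadmium 0.22, DMA
0.28, cobalt −0.14, MMA −0.10, barium 0.05, plus two negative
interactions at −0.15), noise_sd = 0.19, and 5% LOD censoring. The
resulting SD(log10 outcome) ≈ 0.27 and truth correlation ≈ 0.64 — a
*stronger* signal than real cohorts show (observed correlations there
are ≈ 0.2–0.35), because the generative truth has none of the
measurement error, residual confounding, and shrinkage that attenuate
empirical fits. Green recovery tests therefore establish that the
engines find structure that is present; they do not establish
performance at real-data signal-to-noise. The generator also does not
emulate survey sampling weights, oversampling, cycle structure, or
missing-data patterns (files are read complete-case).

## Determinism and I/O

Every stochastic routine takes an explicit seed (numpy Generator); the
same (config, seed) reproduces cohorts, splits, fits, and output files
byte for byte. Output CSVs carry the run seed and a config hash (output
path excluded) in a header comment and contain no timestamps. CSV dialect:
comma, UTF-8, "." decimal, `%.12g` floats. The interaction column-name
grammar `A`, `AxB` is part of the public API.

## Known limitations

* Post-selection SEs/p-values are approximate (selection treated as
  fixed); no debiased-lasso machinery.
* The sum-of-trees and kernel samplers favor mixing-friendly
  simplifications over draw-for-draw reproduction of any particular
  published implementation.
* Exact kernel fitting is O(n³)/iteration; large cohorts are subsampled.
* The quintile OR is undefined (error) when an extreme quintile is empty
  in the test set, and unstable under quasi-separation.
* Binary-outcome super learning, E×Z interactions, competing risks, and
  survey-weighted inference are out of scope.
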