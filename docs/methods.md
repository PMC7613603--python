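# Methods

`pairjm` implements a complete analysis chain for nine correlated binary
quality-of-care indicators recorded on patients nested in clinicians nested
in hospitals, in the setting of a cluster-randomized audit-and-feedback
trial: multilevel multiple imputation of missing covariates, pairwise
pseudo-likelihood estimation of a correlated random-intercept joint model,
Rubin's-rules pooling, joint Wald tests, and association/PCA summaries of
the random-intercept covariance. This note records the models, the
numerical choices, and what the synthetic-data experiments do and do not
establish.

## The joint model and its pairwise estimator

For outcome r (r = 1..p) of patient i seen by clinician j,

    logit P(Y_rij = 1) = x_ij' beta_r + b_rj ,
    (b_1j, ..., b_pj) ~ N(0, D),

with a common 13-term fixed-effect design (intercept; patient age group,
sex, three comorbidity-count contrasts against the ">= 3" reference;
clinician cadre and sex; hospital admission workload and malaria
endemicity; calendar time, trial arm, time x arm). Conditional on b the
outcomes are independent, so the cluster contribution is a p-dimensional
integral. The p x p covariance D carries the scientific signal about how
indicators co-vary across clinicians; its scaled off-diagonals are the
outcome associations.

Fitting all p = 9 outcomes at once requires 9-dimensional quadrature, which
is the computational wall this methodology exists to avoid. Instead all
Q = p(p-1)/2 = 36 bivariate models are maximized separately. The stacked
estimate maximizes the pseudo-log-likelihood (the sum of the pairwise
log-likelihoods) and is asymptotically normal with sandwich covariance
H^{-1} G H^{-1}; each outcome's p-1 duplicate coefficient vectors are then
averaged by the 0 / 1/(p-1) weight matrix A (equal weights, the standard
choice when all pairs are fitted on the same subjects):

    beta* = A beta_stacked,    Sigma* = A Omega A'.

Equal weighting loses some efficiency against the full-joint MLE; the
package quantifies this at p = 3, where the full model is still tractable
as a testing oracle (see "Study sizes" below). `full_joint_fit` refuses
p > 3 by design — it exists to validate the pairwise path, not to replace
it.

### Two sandwich constructions

`sandwich_empirical` (default) builds the bread from per-cluster observed
informations of each pairwise fit (block-diagonal across pairs) and the
meat from per-cluster scores concatenated across pairs, aligned on
clinician id, so cross-pair blocks of G capture the dependence between
pairs sharing an outcome. Clusters absent from a pair (possible after
filtering) contribute zero score blocks. The stored `omega` is the
finite-sample covariance (sums, not averages, inside the sandwich), so
standard errors are the square roots of its diagonal directly; normalized
H and G are kept alongside for inspection.

`sandwich_literal_recipe` reproduces the originally described step-by-step recipe literally
in which the middle matrix is T = Z D Z' with no inverse and no Bernoulli
residual-variance term. As printed, its "J" blocks are not Hessian
analogues (setting Z = 0 makes J = 0, and the formula has the wrong limits
in general), so the routine emits a warning and exists for side-by-side
comparison, not inference. The discrepancy is documented rather than
silently repaired.

### Wald tests and pooling

Joint covariate effects are tested with (L beta)'(L V L')^{-1}(L beta)
against chi-squared with rows(L) degrees of freedom — one row per outcome
(9 df at full scale; the comorbidity covariate tests its three contrasts
simultaneously, 3p rows). No small-sample F/degrees-of-freedom adjustment
(e.g. Rubin-Li-Raghunathan) is applied to the MI statistic, and no
multiplicity correction is made across the ten covariate-level tests; both
choices mirror the source analysis and are limitations for small M.

Across M imputations, Rubin's rules give beta_bar = mean(beta*_m),
V = W + (1 + 1/M) B with W the mean within-imputation covariance and B the
full between-imputation covariance matrix (retained as a matrix so joint
Wald tests after MI are well defined).

## Maximum likelihood by adaptive Gauss-Hermite quadrature

Each (univariate, bivariate, trivariate) likelihood is evaluated with
tensor-product Gauss-Hermite quadrature adapted per cluster: the integrand's
mode is found by a (vectorized, step-clipped) Newton iteration — the
conditional log-posterior is concave — and nodes are centered and scaled by
the mode and the inverse curvature Cholesky factor. Defaults: 15 nodes per
dimension for production fits; the suite's quadrature-convergence check
(15 vs 25 nodes, < 1e-4 on fixtures) justifies the smaller node counts
(5-9) used in replicated simulation studies, where random-intercept SDs
are near 1 and quadrature error is orders of magnitude below sampling
noise.

Gradients use Fisher's identity — the marginal score equals the posterior
expectation of the complete-data score — evaluated with the same nodes and
posterior node weights. This gives per-cluster score vectors as a
by-product, exactly what the pseudo-likelihood sandwich needs. D is
parameterized by its log-Cholesky factor (log on the diagonal), keeping it
positive definite throughout; boundary fits (variance < 1e-3, |corr| >
0.99) and non-convergence are flagged on the result, never dropped.
Optimization is L-BFGS-B from outcome-wise ordinary logistic starts
(statsmodels GLM) with random-intercept variances 0.5 and covariance 0;
replicated studies warm-start each replicate at the previous solution.
Per-cluster Hessian blocks are central finite differences of the
per-cluster scores with step 1e-5 (1 + |theta|).

A numerically zero D degenerates the likelihood to independent ordinary
logistic regressions evaluated at b = 0 (used by tests as an analytic
reduction).

## Two-level latent-normal imputation

Missing binary covariates are represented by latent normals thresholded at
zero: patient-level targets get residual variance fixed at 1 (probit
identification) plus a clinician random intercept; clinician-level targets
carry their variability entirely through the clinician-level random effect
(no separate level-2 residual — the level-2 model is written without one,
and it is implemented as written). The random effects of all targets are
jointly N(0, Sigma_b), which is what lets observed patient-level data
inform missing clinician-level values and vice versa.

The Gibbs sampler updates, per sweep: truncated-normal latents for observed
cells (inverse-CDF sampling; the truncation side is the observed category),
unconstrained latents for missing cells; clinician effects from their
normal full conditionals; regression coefficients with flat priors (level 2
via GLS against the conditional covariance of its random effects given
level 1); and Sigma_b from an inverse-Wishart full conditional (identity
scale, degrees of freedom = dimension — a minimal proper prior; the source
software does not print its priors, so these are this package's choice).
Completed datasets are saved at sweeps burn_in + m * between; observed
cells are never altered. Predictors include the fully observed covariates
and all p outcomes at both levels — outcomes enter level 2 as cluster
means, the standard aggregation when the source is silent on it. Collinear
predictor columns are pruned by pivoted QR before sampling (common in small
simulated cohorts where hospital-level indicators can coincide).

Production settings are M = 20, burn-in 500, 500 between draws; the desk
and test runs shorten the chain (values below). Trace diagnostics (lag-1
autocorrelation, autocorrelation-adjusted half-chain drift) are emitted as
data; no automatic pass/fail decision is made.

Only the collapsed two-level cadre (clinical vs medical officer) is
imputed; a multi-category latent representation is unnecessary because the
generator produces the collapsed variable directly and the analysis model
uses it.

## Association and PCA

The assembled D averages each outcome's p-1 pairwise variance estimates
onto the diagonal and maps each pair's covariance to its cell; under MI the
M assembled matrices are averaged entrywise. Assembly does not guarantee
positive semidefiniteness — violations are flagged, and a nearest-PSD
eigenvalue clip is available but never applied silently.

`pca_correlation` offers two conventions. "eigen" is the textbook
eigendecomposition of the correlation matrix with proportions lambda/p.
"column_standardized" treats the p x p correlation matrix as a data matrix
of p observations and runs a centered, column-scaled PCA on it (what R's
`prcomp(C, scale.=TRUE)` computes when handed the matrix directly); this is
the convention that reproduces the reported first/second-component
percentages for the trial's published matrices (57.6/24.6 complete-case;
60.3/26.2 after MI, matched to ~0.8 points, consistent with two-decimal
table rounding), and it is therefore what the acceptance computation uses.
Loadings are eigenvectors scaled by sqrt(lambda) with the largest-magnitude
loading of each component made positive.

## The synthetic-data generator

The trial's records are not deposited, so a generator emulates the study
conditions; its defaults are the published design figures, not tuning
knobs. 12 hospitals, half randomized to enhanced audit-and-feedback;
5/12 in high-malaria regions; half high-workload (the published text
categorizes workload but not the split; an even split is assumed).
Clinicians per hospital: 1 + negative binomial with mean 32, dispersion 8.
Patients per clinician: 3 + negative binomial with mean 5.6 (2127/378),
dispersion 2, capped at 46 — matching the printed mean and range without
claiming the unprinted distribution. Covariate marginals are the printed
descriptives (age 2-11 months 42.5%, male 55.1%, comorbidity
46.8/29.8/17.9/5.5%, clinical-officer cadre 64.4%, female clinicians
43.2%). Admission time is uniform over 0-8 months (the trial ran
March-November; the admission-time distribution is unprinted). Covariates
are sampled independently within level — their joint distribution is
likewise unprinted.

The default D is the covariance implied by the published MI
variance-correlation table, eigenvalue-clipped to the PSD cone (the
published matrix, assembled from pairwise fits, has one slightly negative
eigenvalue). Non-intercept fixed effects are modest shared values (the
time x arm interaction is +0.15 for the six indicators reported to improve
under the intervention, 0 otherwise; patient sex 0, matching its
non-significant joint test). Intercepts are calibrated by root-finding so
each indicator's marginal prevalence matches its published documentation
rate (88.8, 60.9, 69.3, 48.7, 24.6% where printed; the unprinted
assessment indicators are set to 0.97/0.95/0.80/0.85, consistent with
"well documented"). Missingness defaults: patient sex MCAR at 17/2127;
cadre MAR at 82/378 with a mild workload dependence (log-odds slope 0.5,
intercept calibrated to the marginal rate); clinician sex coupled to cadre
(P(sex missing | cadre missing) = 0.95, residual rate solved so the
marginal is 83/378) — reproducing the near-coincident missingness of the
two clinician variables.

`desk_params` is a small configuration (~6 hospitals, ~60 clinicians) with
moderate outcome prevalences (0.35-0.65); the full-scale near-one
documentation rates would separate a 13-term logistic design at a few
hundred patients, so desk-scale realism is traded for identifiability.

What passing tests on these data do not show: robustness to MNAR
missingness, to covariate joint structure (e.g. cadre mix differing by
hospital), to non-logistic link misspecification, or to the clinical
derivation of the indicators from raw measurements — none of which the
generator simulates.

## Study sizes used by the replicated checks

Chosen once as desk-scale versions of the analysis, balancing Monte-Carlo
resolution against a single-CPU run:

- Oracle equivalence (pairwise average vs full-joint MLE): p = 3, 30
  replicates of 200 clusters x 8 patients, 4-term design; full joint with
  5 nodes/dimension, pairwise with 7. Pass criterion: the mean difference
  per coefficient is within 3 empirical SEs of the MLE and an order of
  magnitude smaller than the estimator's own sampling SD.
- Parameter recovery and SE calibration: 50 replicates of 400 clusters x
  10 patients, bivariate, 7 nodes; bias within 3 SEs of the replicate
  mean; sandwich SE within 20% of the empirical SD plus a 2-sigma
  Monte-Carlo allowance for the SD estimate itself.
- MI calibration: 100 replicates of a ~48-clinician cohort, p = 3, M = 5,
  Gibbs burn-in 80 / 40 between, 8-term design, 5 nodes; pooled 95%
  intervals must cover the generating coefficients in 90-98% of replicates
  for the missingness-affected covariates, and the mean pooled SE must not
  exceed the mean complete-case SE.

## Known limitations

- ML with pseudo-likelihood asymptotics; no Bayesian fitting path.
- Chi-squared reference for all Wald tests (no F/df small-sample
  adjustment), and no multiplicity control across covariates.
- Random intercepts only (no random slopes, no hospital-level effects),
  logit link only, by scope.
- The verbatim sandwich recipe is reproduced for comparability but is not
  a valid variance estimator as printed.
- MNAR sensitivity analysis and multiple outputation are out of scope.
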