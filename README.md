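# pairjm

Pairwise pseudo-likelihood joint modeling of clustered binary outcomes,
with multilevel latent-normal multiple imputation of missing covariates.

## The problem

Routine-care studies often record many binary quality-of-care indicators
per patient — here, nine pediatric pneumonia indicators (documentation of
cough, difficult breathing, respiratory rate, oxygen saturation, AVPU and
chest-wall indrawing; correct diagnosis; amoxicillin prescription; correct
dose) for children admitted to 12 Kenyan hospitals during a
cluster-randomized audit-and-feedback trial. Questions like "does the
intervention improve care across all indicators jointly?" and "how strongly
do indicators co-vary across clinicians?" need a joint model:

    logit P(Y_rij = 1) = x_ij' beta_r + b_rj,   (b_1j ... b_pj) ~ N(0, D)

with clinician-level random intercepts correlated across the p = 9
outcomes. Fitting this directly requires 9-dimensional integration, so the
model is estimated pairwise: all Q = p(p-1)/2 = 36 bivariate generalized
linear mixed models are maximized separately (adaptive Gauss-Hermite
quadrature), the 936 stacked coefficients are averaged into 117 joint-model
coefficients by a 0 / 1/(p-1) weight matrix A, and inference uses the
pseudo-likelihood sandwich covariance H^-1 G H^-1 built from per-cluster
scores and Hessians:

    beta* = A beta_stacked,    Sigma* = A (H^-1 G H^-1) A'.

Covariates are incomplete (patient sex 0.7%; clinician sex 21.9% and cadre
21.7%, nearly always missing together), so analyses run on M multiply
imputed datasets — a two-level latent-normal joint model fitted by Gibbs
sampling, with all nine outcomes as auxiliary predictors at both levels —
and are pooled by Rubin's rules, V = W + (1 + 1/M) B. Joint covariate
effects are tested with Wald statistics (L beta)'(L V L')^-1 (L beta)
against chi-squared with one degree of freedom per outcome, and outcome
associations are read off the assembled 9x9 random-intercept covariance
(correlations, then PCA of the correlation matrix).

The trial's records are not publicly available, so the package ships a
synthetic-data generator whose defaults emulate the study's structure
(hierarchy, covariate marginals, documentation rates, missingness pattern);
every statistical claim is exercised end to end on such data. See
`docs/methods.md` for models, priors, numerics and limitations.

## Worked example

```python
import pairjm

# a small synthetic cohort: 3 outcomes, ~60 clinicians, MAR missingness
params = pairjm.desk_params(p=3, seed=1)
data = pairjm.generate(params)

# impute, fit all pairs per dataset, combine, pool, test
cfg = pairjm.PipelineConfig(p=3, M=5, burn_in=100, between=50,
                            n_quad=9, seed=20160303)
res = pairjm.run_pipeline(cfg, "results/run_desk")
print(res["wald"][["covariate", "df", "stat_mi", "p_mi"]])
```

prints (desk-scale synthetic data, so statistics differ from the trial's):

```
       covariate  df   stat_mi     p_mi
      age_2_11mo   3  2.371209 0.499017
    patient_male   3  2.172952 0.537296
     comorbidity   9 11.876851 0.220341
clinician_female   3  1.657920 0.646329
        cadre_co   3  9.178101 0.027014
   high_workload   3  3.067368 0.381354
    high_malaria   3 15.042191 0.001781
     time_months   3  2.594867 0.458390
             arm   3  6.572170 0.086859
      time_x_arm   3  4.833309 0.184418
```

Each row is one covariate's joint test across the three outcomes: the
chi-squared statistic, its degrees of freedom (one per outcome; the
comorbidity row tests its three contrasts in every outcome), and the
p-value after multiple imputation. In this run clinician cadre and
hospital malaria endemicity show joint effects at the 5% level. `results/run_desk/` also holds
the per-coefficient odds-ratio tables (complete-case and pooled side by
side), the assembled random-intercept variance-correlation tables, and the
PCA summary.

The numbered drivers under `analysis/` walk the full story at larger scale:
`01_simulate.py` (trial-shaped cohort and the 7.5% record-exclusion
filter), `02_impute.py`, `03_fit_and_pool.py`, `04_wald_tests.py`,
`05_association_pca.py`. A CLI mirrors the stages
(`pairjm simulate|impute|fit-pairwise|run|report ...`).

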