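# trajmix

Trajectory-*shape* clustering of longitudinal outcomes, built for questions
like: *is prenatal chemical exposure associated with how a child's BMI
changes between ages 2 and 9, rather than with its level?*

Standard growth-mixture and group-based trajectory models cluster repeated
measures mostly by outcome level, because the level dominates between-subject
variability. `trajmix` first removes each subject's level by subtracting
their own mean over observed visits, then fits a finite multivariate
Gaussian mixture to the centered trajectories, so the latent groups capture
developmental *patterns* (rising early, rising late, flat, ...). Baseline
risk factors — e.g. log10 lipid-adjusted serum concentrations of
organochlorine compounds — enter the mixing proportions through a
multinomial logit, and associations are reported as relative risk ratios
(RRR) with Wald confidence intervals.

## Model

For subject *i* with visit ages *t<sub>i</sub>*, centered outcomes
*y<sub>i</sub>*, and baseline covariates *z<sub>i</sub>*:

```
f(y_i | t_i, z_i) = Σ_k  π_k(z_i) · N( y_i ; X_i β_k , Σ_k(t_i) )
```

* **X<sub>i</sub>** — quadratic B-spline basis at the subject's ages, one
  internal knot at the pooled median age (4 basis functions);
* **β<sub>k</sub>** — group-*k* mean-curve coefficients;
* **Σ<sub>k</sub>** — working covariance: `independence` (σ²I) or
  `exponential` (σ² exp(−Δt/φ)), constant variance;
* **π<sub>k</sub>(z)** — multinomial-logit membership probabilities; the
  last group is the reference.

Estimation is multi-start EM; the number of groups K and the covariance
structure are chosen by minimising BIC = −2ℓ + d·log n (n = subjects);
subjects are classified to their maximum-posterior group. For group *j* vs
the reference group *K*, a δ-unit covariate increase has

```
RRR_j = [π_j(z+δ)/π_j(z)] / [π_K(z+δ)/π_K(z)] = exp(δ·γ_j)
```

with standard errors from the observed information of the full mixture
likelihood, so classification uncertainty propagates into the intervals.

Because the restricted cohort data that motivated the package cannot be
shipped, `trajmix.simulate` generates labelled synthetic cohorts with the
same structure (5 nominal visit ages, ≥4-visit inclusion rule, four shape
groups, subject-level offsets, exposure-driven membership), so the whole
pipeline is testable end to end.

## Worked example

```python
import trajmix as tm

cohort   = tm.simulate_cohort(tm.default_cohort_scenario(seed=7, n_subjects=250))
centered = tm.center_trajectories(cohort.panel)

best, table = tm.select_model(centered, seed=7, n_starts=4)
print(table)                       # BIC over K ∈ {2..5} × covariance kinds
```

```
 K     cov_kind       loglik  n_params         bic  converged
 2 independence -1735.943842        11 3532.623754       True
 3 independence -1551.322947        17 3196.510729       True
 4 independence -1495.960050        23 3118.913702       True   <- minimum
 5 independence -1485.522166        29 3131.166699       True
 ...
```

BIC picks **K = 4 groups with independence covariance**: adding a fifth
group improves the log-likelihood too little to justify six extra
parameters. Classification and the exposure association:

```python
labels, unc = tm.classify(best)                  # group sizes [29, 51, 85, 85]
design = tm.build_design(cohort.baseline, centered.subjects,
                         exposures=["log10_dde"])
refit  = tm.refit_with_covariates(centered, design, K=4,
                                  cov_kind="independence", seed=7, base_fit=best)
print(tm.wald_ci(refit, "log10_dde"))
```

```
       gamma     se    rrr  ci_low  ci_high  p_value
group
1      0.805  0.451  2.237   0.924    5.415    0.074
2      1.295  0.385  3.653   1.717    7.768    0.001
3      1.227  0.342  3.413   1.745    6.675    0.000
```

Read: a ten-fold increase in the exposure multiplies the odds of belonging
to group 2 ("stable then rising from ~age 4–5") rather than the flat
reference group by ≈3.7 (95% CI 1.7–7.8). The generating scenario put the
strongest exposure effects on the late-rising groups, and that is what the
refit recovers.

A command-line interface wraps the same steps
(`trajmix simulate | fit | select | associate | run`); `trajmix run
--config cfg.yaml --out-dir out/` executes the full pipeline — filtering,
sex stratification, centering, selection, classification, adjusted and
unadjusted RRR tables, sensitivity subsets — and writes CSV outputs plus a
reproducibility manifest.

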