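# Methods

## The problem and the transformation

Repeated anthropometric measures (here BMI, kg/m², at nominal ages 2, 3.5,
5, 7, 9 years) mix two kinds of between-child variability: the *level* of
the outcome and the *shape* of its change over age. Mixture-model
clustering applied to raw trajectories is dominated by level. `trajmix`
removes the level first: each subject's observed-visit mean is subtracted,
so a child at BMI 15 and a child at BMI 22 with parallel trajectories
become identical centered curves. Clustering then targets developmental
pattern, and the association analysis asks whether baseline risk factors
shift the probability of *pattern* membership.

The subject mean is an estimate of the level computed from the same data,
so centering is a working transformation, not an orthogonal projection of
the model: after centering, a subject's residual vector sums to zero, and
its true covariance is singular (rank d−1). We nonetheless fit nonsingular
working covariances (independence or exponential) on the centered data.
This is deliberate: the mixture is a descriptive device for grouping
shapes, and the working-model likelihood is what BIC and the posteriors
are defined on. The main practical consequence is that the fitted σ² is a
working parameter, slightly smaller than the generating noise variance
(the centering projection removes 1/d of it, and visit-missingness varies
d across subjects).

## Model

Centered outcomes y_i at ages t_i with covariates z_i:

f(y_i | t_i, z_i) = Σ_k π_k(z_i) N(y_i; X_i β_k, Σ_k(t_i)),

- X_i: quadratic B-spline basis (degree 2, one internal knot at the pooled
  median observed age, boundary knots at the observed range; dimension 4).
  The basis comes from `scipy.interpolate.BSpline.design_matrix`; rows are
  non-negative and sum to one inside the boundary. Mean curves are pure
  spline combinations with no separate intercept — centered data make a
  free intercept nearly redundant.
- Σ_k: `independence` σ²_k I or `exponential` σ²_k exp(−|Δt|/φ_k), constant
  variance across visits. Covariance parameters are group-specific; no
  sharing across groups (configurable in principle, but group-specific is
  the default and the tested path).
- π_k(z): multinomial logit with the last group as reference; γ is
  (K−1) × (1+p).

Subjects with a single observed visit carry no shape information after
centering and are dropped with a warning. Subjects enter a fit only with
at least `min_visits` (default 4) observed visits.

## Estimation

EM with unequal-length observation vectors, vectorised over groups of
subjects sharing a visit-age pattern (with 5 nominal ages and a 4-visit
floor there are at most 6 patterns).

- E-step in the log domain (log-sum-exp); posteriors never under/overflow.
- M-step, means: posterior-weighted GLS; the normal equations are solved
  by least squares, so a rank-deficient pooled design (fewer distinct ages
  than basis functions) yields the minimum-norm solution with a warning
  rather than an error — the likelihood depends only on Xβ.
- M-step, covariance: independence has the closed-form weighted mean
  squared residual. For the exponential kind, σ² has a closed form given
  φ, and the profile likelihood is scanned over a fixed 61-point grid in
  log φ ∈ [log 0.01, log 100] (years), followed by one parabolic
  refinement evaluated exactly; the incumbent φ is always a candidate, so
  the step never decreases the likelihood. Correlation Cholesky factors on
  the grid are precomputed once per fit.
- M-step, membership: posterior-weighted multinomial Newton iterations
  with step halving (closed form for intercept-only designs). Log-odds are
  capped at |η| ≤ 30 with a warning under quasi-separation; in practice
  Newton's gradient vanishes numerically before the cap binds.
- Convergence: relative log-likelihood change < 1e−8 (default), cap 500
  iterations. The trace is non-decreasing up to ~1e−12 per step because
  every M-step is an exact (or candidate-safeguarded) maximiser.
- Multi-start: one deterministic k-means partition of visit-aligned
  centered vectors (missing visits column-mean imputed) plus random
  Dirichlet responsibilities, 20 starts by default. All starts run a short
  screening phase (25 iterations); the best few (default 3) continue to
  convergence and the best final log-likelihood wins. This emEM-style
  screening cuts runtime several-fold without changing which basin wins in
  practice; the tiny-instance tests confirm agreement with a direct
  numerical maximiser of the same likelihood to ~1e−9.
- Label switching: groups are relabelled by the fitted mean-curve value at
  the oldest observed age, descending, so group 1 is the steepest riser
  and group K the flattest — a convention that matches how such groups are
  usually reported.
- Variances are floored at 1e−8; hitting the floor flags the fit.

Model selection fits every (K, covariance kind) cell without covariates
and minimises BIC = −2ℓ + d log n with n = the number of subjects — the
mixture's independent units — and d = Kq + Σ_k (1 or 2) + (K−1)(1+p).
Using observations instead of subjects as n would penalise harder and bias
selection toward smaller K; subjects are the defensible unit because the
likelihood factorises over them.

## Association and inference

After (K, covariance) are fixed, covariates enter the membership model and
the *entire* mixture is re-estimated jointly (means, covariances, γ), warm
started from the covariate-free posteriors plus random restarts. The RRR
for group j vs the reference per δ-unit covariate increase is exp(δγ_j) —
constant in z under the multinomial logit, verified against the defining
probability-ratio identity in the tests.

Standard errors come from the observed information of the full mixture
log-likelihood at the MLE, computed by central-difference numerical
differentiation (step 1e−4 on each parameter's natural scale, shrunk for
variance parameters to stay in-domain). This propagates classification
uncertainty into the intervals; the cheaper two-stage variant (multinomial
information with hard max-posterior labels, `method="two_stage"`)
understates uncertainty and is provided only for comparison. Confidence
intervals are symmetric on the log scale, exp(γ ± z_{α/2} SE); two-sided
Wald p-values are reported without multiplicity correction. Exposures are
entered one at a time, unadjusted and then adjusted for the configured
confounders; interactions are scanned one modifier at a time, comparing
BIC with and without the product term.

Covariate missingness is handled complete-case per model, with a logged
count of dropped subjects.

## Synthetic cohorts

The generator draws, per subject: baseline covariates, a latent group via
multinomial logit on those covariates, a Normal level offset (SD 1.5
kg/m²), visit-wise missingness (probability 0.05 per visit, hard floor of
4 retained visits — matching the per-visit attrition of cohorts with a
"≥4 of 5 visits" inclusion rule), and within-subject noise (independence
σ² = 0.49, i.e. SD 0.7 kg/m², or exponential with φ = 1.5 years). Values
are group base level + group shape curve(age) + offset + noise. Each
subject has a deterministically derived RNG substream, so cohorts are
bit-reproducible and invariant to iteration order.

The default four-group scenario uses shape-preserving (PCHIP) curves
through per-visit anchors that echo the four canonical patterns — linearly
rising; stable then rising from ~age 4–5; stable then rising from ~age
6–7; flat — with marginal group proportions ≈ (0.16, 0.18, 0.31, 0.35)
at the covariate means, a log10 serum-exposure covariate (mean 3.15, SD
0.53 log10 ng/g lipid) whose effects are strongest for the late-rising
groups, and four confounders (maternal pre-pregnancy BMI, years in the
USA, breastfeeding months, birth weight in kg) with small effects.

What the generator does *not* emulate: real assay left-censoring
(covariates are drawn directly on the log10 scale), informative or
subject-level dropout (missingness is visit-wise at random), age-varying
noise variance, measurement error in ages, and curves outside the smooth
PCHIP family. Passing tests therefore demonstrate that the estimation
machinery recovers the structure it assumes — not that real cohort data
satisfy those assumptions.

## Numerical design notes

- **Exact centering.** The per-subject mean and its subtraction are
  computed in exact rational arithmetic (`fractions.Fraction`) with one
  correct rounding per output value. Consequences: centered values sum to
  zero per subject to ≤ a few ulp; un-centering recovers the input bits
  whenever the centered magnitude is below the raw magnitude (always, for
  anthropometric data); and adding a subject-specific constant whose
  float addition is exact leaves the centered panel — and hence every
  downstream estimate under a fixed seed — bit-identical. The invariance
  test constructs offsets on a dyadic grid precisely so the addition is
  exact; for arbitrary float offsets the discrepancy is limited to the
  last ulp of the inputs.
- Ages are used as recorded (no rounding to nominal visits); patterns are
  grouped on ages rounded to 1e−9 only for exact-tie detection.
- Degenerate e-step/likelihood cases (all components far) are handled by
  log-sum-exp; no NaNs are produced for valid parameters.
- `select_model`, the pipeline, and the acceptance script derive all cell
  seeds from one root seed via `numpy` `SeedSequence`, so results are
  reproducible and order-invariant.

## Problem sizes in the shipped checks

The test suite and acceptance script use cohorts of 250 subjects per
selection replicate (5–10 replicates), 800 subjects per
parameter-recovery replicate (25 replicates), 30-subject instances for
the direct-maximiser comparison, and ~70-subject cohorts for the
monotonicity sweep. These sizes were chosen to put each check's Monte
Carlo error well inside its decision margin while keeping a full run in
the minutes range on a single CPU.

## Limitations

- The working covariance on centered data is misspecified by construction
  (singular truth, nonsingular model); σ̂² is not an unbiased estimate of
  the generating noise variance.
- BIC selection treats the number of subjects as the sample size; with
  very unequal visit counts other conventions exist.
- Wald intervals rely on asymptotic normality at an interior optimum; they
  degrade near separation or a variance floor (both are flagged).
- No multiple-imputation for missing covariates; complete-case only.
- One internal knot and constant variance are fixed by design; more
  flexible mean or variance structures are out of scope.
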