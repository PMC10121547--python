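# Methods

## Model

For observation i with covariate row x_i = (1, x_{1i}, …, x_{pi})', the
response is Gaussian with both moments regressed on covariates:

    y_i ~ N( x_i' β, exp(x_i' α) ).

The log-linear variance keeps σ_i² positive, and a coefficient of exactly
zero removes a covariate from that component only, so the location and
dispersion supports may differ.  Because a single penalty weight is applied
to every coefficient, predictors must be on a common scale; `Dataset`
divides each predictor column by its sample standard deviation (ddof = 1)
and records the divisors, and reports can be mapped back with
`unscale_coefs`.  Columns are scaled but not centred — centring would only
change the intercept's interpretation, and the intercepts are unpenalised
anyway.

## Smooth information criterion

Model selection criteria have the penalised form −2ℓ(θ) + λ·(model size),
with λ = 2 (AIC) or log n (BIC).  Writing the size as the L0 norm of the
non-intercept coefficient vectors and replacing the non-differentiable
indicator by φ_ε(x) = x²/(x² + ε²) yields the objective that is maximised
directly:

    ℓ^SIC(θ) = ℓ(θ) − (λ/2)·[ Σ_j φ_ε(β_j) + Σ_j φ_ε(α_j) + 2 ].

φ_ε is even, lies in [0, 1), has closed-form first and second derivatives,
and converges pointwise to the zero-indicator as ε → 0.  The "+2" accounts
for the two intercepts; it is constant during optimisation but is kept in
reported SIC values so they are comparable with BIC values at ε → 0.
λ defaults to log n; the AIC variant only changes the constant.

## Optimisation: RS block Newton with ε-telescoping

The score and observed information have closed forms.  Each Newton update
solves the two decoupled systems (the RS scheme — cross-derivative blocks
between β and α are dropped from the left-hand side, motivated by the
information orthogonality of location and scale in the normal model):

    (X' W_β X + λΣ_β/2) Δβ = X' z_β − λν_β/2,
    (X' W_α X + λΣ_α/2) Δα = X' z_α − λν_α/2,

with W_β = diag(e^{−x'α}), W_α = diag(e^{−x'α} r² / 2), z as the
standardised residual scores, and ν/Σ the φ_ε gradient/curvature diagonals
(first entries zero: intercepts unpenalised).  Initial values are OLS for β
and α⁰ = (log s², 0, …, 0) with s² = RSS/(n − p).

A fixed small ε is unstable (the surrogate is nearly discontinuous at 0),
while a large ε does not shrink.  The telescope therefore runs the Newton
solver to convergence at each ε of a geometric sequence ε₁ r^t,
t = 0 … T−1, warm-starting each problem at the previous solution.  Defaults:
ε₁ = 10, ε_T = 1e−5, T = 100, giving r = (ε_T/ε₁)^{1/(T−1)} ≈ 0.87.  After
the final step, coefficients with magnitude below `zero_tol` = 1e−8 are set
to exactly zero (in practice nulls land around 1e−10 — shrinking further is
possible by lowering ε_T).  Thresholding happens once, after the telescope,
never during it.

Numerical safeguards, in order:

- the log-variance linear predictor is clamped to [−30, 30] before
  exponentiation (exp(±30) brackets any realistic variance in double
  precision); clamp events are counted in `FitResult.n_clips`;
- φ_ε'' is negative for |x| > ε/√3, so a penalised block can be indefinite;
  if its Cholesky fails, the penalty curvature is replaced by its absolute
  value for that step (the objective check below still governs acceptance);
- a block with condition number above 1e12 receives a ridge of
  1e−8 × mean(diag) on its diagonal;
- the joint step is halved (at most 20 times) until the SIC objective does
  not decrease; if no step length helps, the parameters are left unchanged,
  which terminates the inner loop at the current point;
- the inner loop stops when the maximum absolute parameter change is below
  1e−8 or after 100 iterations per ε; non-convergence is recorded in the
  trace, not fatal.

The single-parameter variant (`fit_spr_sic`) runs the identical algorithm
with the non-intercept rows/columns of the α system removed — i.e. a
classical constant-variance penalised linear regression.  The same masking
machinery implements ΔBIC: the restricted model drops one column from one
component's design and re-runs the **full** telescope (not a one-shot refit
at ε_T), and ΔBIC = BIC(restricted) − BIC(full).  An alternating
mean/variance backfitting scheme would also be possible under RS but is not
implemented.

## Inference

The covariance of the penalised estimates is the sandwich
I(θ̂)⁻¹ I₀(θ̂) I(θ̂)⁻¹, where I includes the penalty curvature and the
cross blocks X' W_{αβ} X, and I₀ is the unpenalised observed information.
It is evaluated at the raw (pre-threshold) estimate with ε = ε_T; SEs are
reported for active coefficients only.  With no penalty it collapses to
I₀⁻¹.  For a coefficient shrunk to zero the penalised information is
dominated by λφ''(0)/2 = λ/ε_T², so its sandwich variance is effectively
zero — consistent with treating it as excluded.

Wald intervals are estimate ± z·SE; prediction intervals are
x'β̂ ± z·exp(x'α̂/2).  For the 95% level z is fixed at 1.96 to match the
convention used when reporting such intervals; other levels use the exact
normal quantile.

## Simulation design and metrics

The reference design has n ∈ {100, 500, 1000} observations on 12 covariates:
(X1, X11) ~ Exponential(1) (skewed), (X3, X10) ~ Bernoulli(0.75)
(unbalanced binary), (X4, X5, X7, X8) ~ N(0,1) independent, and
(X2, X6, X9, X12) a multivariate normal block with corr(Z_j, Z_k) =
0.8^{|j−k|}.  Truth vectors (intercepts first):

    β = (0, 1, 0.5, 0.5, 1, 0.5, 1, 0, 0, 0, 0, 0, 0)
    α = (0, 0.5, 1, 0.5, 1, 0, 0, 0.5, 1, 0, 0, 0, 0)

so covariates enter both components (X1–X4), the location only (X5, X6),
the dispersion only (X7, X8), or neither (X9–X12).  Responses are
y = x'β + exp(x'α/2)·z with z ~ N(0,1).

Each replicate generates a fresh training set, scales predictors by the
training SD, fits, and generates a fresh holdout of size ⌈0.2n⌉ (scaled
with the training factors).  The truth is defined on the generated covariate
scale; estimates are divided by the scaling SDs before comparison.  Child
replicate seeds are spawned deterministically from the design seed via
numpy's SeedSequence, so studies are exactly reproducible.

Metrics per component: C (mean correct zeros, max 6), IC (mean incorrect
zeros), PT (probability of selecting the exact true support), and the
in-sample quadratic-form MSE (θ̂−θ)'X'X(θ̂−θ)/n.  Per coefficient: mean
estimate, empirical SD of estimates (SE), mean estimated SE (SEE; averaged
over replicates where the coefficient is active, since SEs are only defined
for active coefficients), and empirical 95% CI coverage (CP; a
thresholded-to-zero estimate counts as covering iff the truth is zero —
`cp_active_only=True` switches to conditioning on activity).  Out-of-sample
prediction coverage (PCP) is the fraction of holdout responses inside
nominal 95% intervals, overall and stratified by the true σ_i with
thresholds (1, 2.2) — the tertiles of the σ distribution under this design;
for real data, tertiles of the fitted σ̂_i are the natural cutpoints.

Monte-Carlo checks in the test suite and the acceptance script use 200
replicates at n = 1000 — enough that binomial error on a 0.95 proportion is
about ±0.015 (1 SE) — and assert with 3–4 SE allowances around the
large-study values.  What these simulations do emulate: mixed marginals,
strong covariate correlation, weak-vs-strong effects in both components.
What they do not: model misspecification (non-Gaussian errors, mean or
variance nonlinearity), missing data, p growing with n; passing tests
therefore says nothing about robustness to those.

## Known limitations

- The Gaussian family only; GLM-type responses would need new score and
  information blocks.
- The fixed ε_T = 1e−5 takes no account of sample size; very small n with
  many covariates (e.g. n = 100 with 26 parameters here) shows the expected
  degradation: under-coverage and occasional loss of weak effects.
- Best-subset equivalence is only verified exhaustively for p ≤ 3 (the
  2^{2p} enumeration is exponential); for larger p the procedure is a
  heuristic for the non-convex IC optimum, albeit one that matched the
  exhaustive oracle in every tested instance.
- ΔBIC refits re-run the whole telescope, so reporting it for every active
  coefficient costs one extra fit per coefficient.
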