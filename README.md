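# sicreg — smooth-IC variable selection for heteroscedastic Gaussian regression

`sicreg` fits normal *distributional* (multiparameter) regression models in
which covariates enter both the mean and the log-variance,

    y_i = x_i' β + ε_i,      Var(ε_i) = σ_i² = exp(x_i' α),

and performs variable selection in both components simultaneously by
maximising a **smooth information criterion** (SIC): a BIC-type penalised
log-likelihood

    ℓ^SIC(θ) = ℓ(θ) − (log n / 2) · [ ‖β̃‖₀,ε + ‖α̃‖₀,ε + 2 ],

where the L0 cardinality penalty is replaced by the differentiable surrogate
φ_ε(x) = x²/(x² + ε²) applied to all non-intercept coefficients.  Because
the tuning parameter is fixed in advance (log n for BIC, 2 for AIC), no
cross-validation or grid search is needed — a real advantage in
distributional regression, where each component would otherwise need its own
tuning parameter.  Sparsity is obtained by **ε-telescoping**: the objective
is maximised by block Newton–Raphson over a geometrically decaying sequence
of ε values (default 10 → 1e−5 in 100 steps, decay rate ≈ 0.87) with warm
starts, which squeezes null coefficients below 1e−8 while leaving genuine
effects essentially untouched.  Standard errors come from the sandwich
covariance I(θ̂)⁻¹ I₀(θ̂) I(θ̂)⁻¹, and variable importance is measured by
ΔBIC — the BIC increase from refitting with one selected effect removed
from one component.

The intended users are statisticians and epidemiologists who want
heteroscedasticity-aware model selection with honest uncertainty: the same
machinery also yields per-observation mean–variance pairs (μ(x), σ²(x)) and
95% prediction intervals x'β̂ ± 1.96·exp(x'α̂/2) that adapt to the local
noise level.

## Worked example

Generate one dataset from the built-in simulation design (12 covariates with
mixed Exponential/Bernoulli/normal/AR(1)-correlated marginals; effects of
size 0, 0.5 and 1 in each component) and fit it:

```python
import numpy as np
from sicreg import Dataset, fit_mpr_sic, wald_cis
from sicreg.simulation import SimulationDesign, gen_covariates, gen_response

design = SimulationDesign(n=1000, seed=1)
rng = np.random.default_rng(design.seed)
X = gen_covariates(design, rng=rng)
y = gen_response(np.column_stack([np.ones(design.n), X]),
                 design.beta_true, design.alpha_true, rng)

data = Dataset.from_arrays(y, X)       # predictors scaled to unit SD
fit = fit_mpr_sic(data)                # 100-step telescope, BIC penalty

print(f"BIC = {fit.bic:.1f}, selected {fit.active_beta.size - 1} location and "
      f"{fit.active_alpha.size - 1} dispersion effects")
print(wald_cis(fit).round(3).to_string(index=False))
```

Output:

```
BIC = 3672.1, selected 6 location and 6 dispersion effects
 component  index  estimate    se  lower  upper  level
  location      0     0.055 0.049 -0.042  0.151   0.95
  location      1     1.056 0.030  0.997  1.114   0.95
  location      2     0.533 0.036  0.463  0.603   0.95
  location      3     0.192 0.018  0.156  0.229   0.95
  location      4     1.054 0.020  1.015  1.094   0.95
  location      5     0.496 0.020  0.456  0.536   0.95
  location      6     1.000 0.035  0.931  1.068   0.95
dispersion      0    -0.034 0.100 -0.229  0.162   0.95
dispersion      1     0.561 0.043  0.476  0.646   0.95
dispersion      2     1.101 0.046  1.010  1.191   0.95
dispersion      3     0.169 0.045  0.080  0.258   0.95
dispersion      4     0.973 0.045  0.884  1.062   0.95
dispersion      7     0.504 0.046  0.414  0.593   0.95
dispersion      8     0.958 0.046  0.868  1.047   0.95
```

The fit recovers the exact true support in both components: location effects
on X1–X6 and dispersion effects on X1–X4, X7, X8; all twelve null
coefficients are driven below 1e−8 and set to zero.  Estimates are on the
scaled-predictor scale — e.g. the location coefficient of the Bernoulli
covariate X3 is 0.192 ≈ 0.5 × sd(X3), and `data.unscale_coefs` maps back to
the generated scale.

The same functionality is exposed on the command line for any CSV:

```bash
sicreg fit --data mydata.csv --response y --model mpr --delta-bic --out report/
sicreg simulate --n 1000 --replicates 200 --method mpr --seed 1 --out study/
```

`fit` writes a coefficient table (scaled and original scales, SEs, 95% CIs,
optional ΔBIC), a model summary JSON and the per-ε telescope trace;
`simulate` writes tidy Monte-Carlo metrics (C/IC/PT/MSE, per-coefficient
estimate/SE/SEE/CP, prediction coverage by variability tertile) plus a run
manifest.

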