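# Methods

## Model and estimation

Each study contributes a subvector of the *p* outcomes with a within-study
covariance block that is treated as fixed and known; studies are
independent. True study effects are exchangeable draws around a common mean
with between-study covariance **Σ** (missing outcomes handled through the
marginal normal model for the observed components, assumed missing at
random — not through the older device of notional estimates with huge
variances, which is numerically fragile and only approximates the same
marginal model). Missing components are therefore represented structurally,
by each study's observed index set.

Given **Σ**, coefficients are generalised least squares; **Σ** is estimated
by restricted maximum likelihood by default (full ML available), with the
profile objective

    −2 lR(Σ) = Σᵢ log|Vᵢ| + log|Σᵢ XᵢᵀVᵢ⁻¹Xᵢ| + Σᵢ rᵢᵀVᵢ⁻¹rᵢ + const

minimised over the entries of a lower-triangular square root **Σ** = LLᵀ.
The square-root parameterisation is deliberate: estimated between-study
covariances frequently land on the boundary (a zero variance, a
between-study correlation of ±1), and LLᵀ keeps such points in the interior
of the parameter space of L rather than on a constraint. Structures:
unstructured (default), diagonal, scaled identity.

Numerical choices:

* Optimiser: Nelder–Mead on the square-root parameters, restarted once from
  the incumbent with a fresh simplex (guards against premature simplex
  collapse near the boundary); 500 iterations per stage, convergence when
  the relative objective change falls below 1e−10. Starting values: the
  per-outcome DerSimonian–Laird variances on the diagonal, zero
  correlation, floored slightly above zero. Derivative-free optimisation is
  chosen over quasi-Newton for robustness at boundary optima; the parameter
  count (≤ p(p+1)/2) is tiny.
* Infeasible parameter values during optimisation (a non-PD total
  covariance) return a large finite penalty, never an exception.
* Non-convergence is reported via the `converged` flag plus a
  `RuntimeWarning`; results are returned, never silently discarded.
* Coefficient covariance conventions: `model` is the GLS information
  (Σᵢ XᵢᵀVᵢ⁻¹Xᵢ)⁻¹ with **Σ̂** treated as known; `obsinfo` (default)
  inverts a central-difference Hessian (step max(1e−5, 1e−4·|θ|) per
  parameter) of the full unrestricted log-likelihood in all parameters —
  coefficients and variance components jointly — at the fitted values, and
  takes the coefficient block. The obsinfo block is invariant to how the
  nuisance block is parameterised, so differentiating in the square-root
  parameters is innocuous. Hessian-based standard errors are reproducible
  to roughly two decimals, not bit-exactly.
* Rank-deficient designs (e.g. a constant-zero covariate) are detected from
  the eigenvalues of the total weight matrix (relative threshold 1e−12) and
  raised as errors naming the offending coefficient, never silently
  dropped.
* Positive-definiteness tolerances: within-study blocks must have smallest
  eigenvalue > 1e−12 relative; PSD checks allow −1e−10 relative. Data
  printed to 2–4 significant figures pass comfortably.
* The DerSimonian–Laird τ̂² is truncated at zero, per the univariate
  convention.

## Heterogeneity statistics

* **R** is computed as a log-determinant difference of the selected
  covariance submatrices via LAPACK factorisations (`slogdet`), never by
  determinant cofactors, for stability when C is near-singular (strong
  borrowing of strength).
* **I²_R = (R² − 1)/R²** is truncated at zero and the truncation flagged in
  the entry. Under the `model` covariance convention truncation is
  impossible (R ≥ 1 holds for the full set and every subset whenever **Σ̂**
  is PSD — a property the test suite exercises over random datasets); under
  `obsinfo` it can occur and is logged.
* Reported entries default to the `obsinfo` convention, matching the
  default fit; each entry records which convention produced it, and
  `model`-based entries can be produced by fitting with
  `FitOptions(cov_method="model")`.
* **Qₛ** uses each study's observed block and its fixed-effects residuals;
  v counts observed univariate estimates minus all mean-model coefficients
  (intercepts and covariate effects alike). H² and I²_H are only defined
  for the full coefficient set: the distribution of a subset-restricted Qₛ
  is not well characterised, so subset questions are referred to R / I²_R.
* Per-outcome univariate report: both the Q-based I² (max(0,(H²−1)/H²)) and
  the τ²-based I² (τ̂²_REML/(τ̂²_REML + s²)) are computed and labelled;
  headline per-outcome values use the τ²-based form, which is consistent
  with the REML-based workflow. The per-outcome I² derived from the
  multivariate fit divides the marginal Σ̂ⱼⱼ by itself plus a typical
  within-study variance; the typical variance used is the Higgins–Thompson
  s² over the studies observing that outcome. This is a convention choice
  (alternatives tie the typical variance to multivariate method-of-moments
  estimating equations); with complete data the two agree, with incomplete
  data they may differ, and the report metadata records the convention.
* The t-scaled variant multiplies R by t_{v,(1+γ)/2} / z_{(1+γ)/2} for
  analysts who build random-effects intervals from t quantiles.

## Meta-regression

Covariates are outcome-specific: a covariate may enter any subset of
outcome equations, each with its own coefficient; shared-coefficient
constraints across outcomes are out of scope. With zero covariate terms
every code path is identical to the plain meta-analysis. Qₛ is invariant to
affine reparameterisation of covariates (the fixed-effects fitted values
are), and v drops by exactly one per added term. No small-sample
(Knapp–Hartung-type) adjustment is applied; the t-scaling of R is the only
t-based option.

## Synthetic data

The generator draws, per study: within-study variances uniform on a
per-outcome range, a common within-study correlation, a true effect from
N(μ, Σ), the estimate vector from the within-study normal, then MCAR
masking per outcome. Within-study covariances are drawn once and treated as
known thereafter, mirroring how real within-study covariances are handled
when pooling. Draws leaving any outcome with fewer than two observing
studies are rejected and redrawn (capped at 100 attempts). Defaults emulate
a small bivariate meta-analysis of two correlated continuous endpoints at
the magnitudes of the bundled periodontal example: μ = (0.35, −0.34),
Σ = [[0.012, 0.012], [0.012, 0.033]], within-study variances uniform on
(0.001, 0.02), within-study correlation 0.4, complete data, n = 10.

What the generator does *not* emulate — and hence what passing simulation
tests cannot certify about real data: small-study effects and publication
bias, informative missingness, estimated (rather than known) within-study
covariances, non-normal effect distributions, and outcome counts that vary
systematically with study size.

Problem sizes used in the standing checks: null calibration of Qₛ uses
2000 replicates of a bivariate n = 10 meta-analysis (fixed-effects fits
only, so this is cheap); REML bias is assessed over 200 replicates at
n = 200 with the model-based covariance (the Hessian adds nothing to a
bias check); the R ≥ 1 property over 200 random dataset/Σ̂ draws at
p ∈ {1,2,3}; the univariate reduction over 100 random scalar datasets.

## Known limitations

* No confidence intervals or bootstrap for the heterogeneity statistics;
  they are reported as descriptive quantities.
* No Bayesian or method-of-moments multivariate estimation of Σ.
* Within-study correlations for long-format data must be supplied (zero, a
  common value, or a per-study file); the package does not estimate them.
* The observed-information covariance requires a converged interior-point
  or boundary optimum; for badly conditioned Hessians the model-based
  covariance is the documented fallback.
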