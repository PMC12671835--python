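# Methods

## Model

The Fréchet–Power Function (FPF) distribution lives on a known finite
support `(a, b)`. Writing `v = (x − a)/(b − a)` and `λ = αθ > 0`:

- CDF: `F(x) = (e^(−v^λ) − 1)/(e^(−1) − 1)`
- pdf: `f(x) = λ/((b−a)(1 − e^(−1))) · v^(λ−1) · e^(−v^λ)`
- quantile: `Q(u) = a + (b−a)(−ln(1 + u(e^(−1) − 1)))^(1/λ)`
- survival: `S = 1 − F`; hazard: `h = f/S`

The construction applies the bounded Fréchet-type generator
`u ↦ (e^(−u^α) − 1)/(e^(−1) − 1)` to the Power Function baseline
`F0 = v^θ`. A consequence used throughout: the distribution depends on
`(α, θ)` **only through the product** `λ = αθ`. The score components
satisfy the exact identity `α ∂ℓ/∂α = θ ∂ℓ/∂θ` for every dataset, so the
two shapes are not separately identifiable; only `λ` is.

### Hazard

Some presentations of this family write the hazard in a standalone
closed form that drops the `(1 − e^(−1))` normalization from the
survival denominator; that expression is not equal to `f/S`. This
package always computes `h = f/S` from the pdf and survival function
above — the self-consistent choice. The hazard-shape classifier
evaluates `h` on 2,001 points on `[a + 10⁻⁴(b−a), b − 10⁻⁴(b−a)]`
(avoiding the boundary singularities), marks successive relative changes
below `10⁻⁶` as flat, and maps the compressed sign runs to
increasing / decreasing / bathtub / unimodal / approximately-constant.
More than two runs returns "unclassified" — a signal the flatness
tolerance is too tight for the parameter point, not an error.

### Boundary conventions

The pdf at `x = b` is the finite limit `λ e^(−1)/((b−a)(1−e^(−1)))`, so
data points equal to `b` are admitted in likelihoods. The pdf at `x = a`
is the limit 0 for `λ > 1`, the finite constant for `λ = 1`, and an
error for `λ < 1` (the density diverges). The CDF clamps to {0, 1}
outside `[a, b]` so KS and plotting code can evaluate it anywhere;
`fpf_logpdf` is computed in log space and stays finite where the
density underflows (large `λ` near `a`).

## Moments

All moments reduce to lower incomplete gamma values via `z = v^λ`:
`E[X^r] = (1 − e^(−1))^(−1) Σ_k C(r,k) a^(r−k) (b−a)^k γ(1 + k/λ, 1)`.
The same integral `∫₀¹ z^{k/λ} e^(−z) dz` drives the MGF series; it is
the **lower** incomplete gamma function (the upper reading fails the
`M(0) = 1` check, which the tests enforce). The MGF series truncates
when the next-term bound falls below `10⁻¹²` of the partial sum, with a
200-term ceiling. Skewness and kurtosis are the population quantities
`μ₃/σ³` and `μ₄/σ⁴` from exact moments.

## Sampling

The inverse-transform sampler is the workhorse: `Q(U)` for seeded
uniforms, vectorized. The acceptance–rejection sampler uses a Power
Function proposal `PF(p)` on the same support; with the default
`p = λ` the density ratio `f/g = e^(−v^λ)/(1 − e^(−1))` is monotone with
analytic bound `c = 1/(1 − e^(−1)) ≈ 1.582`, giving acceptance
probability `1 − e^(−1) ≈ 63.2%`. For `p < λ` the bound is found by 1-D
maximization; `p > λ` makes the ratio diverge at the lower endpoint and
is rejected with an explicit error. Each proposal consumes two uniforms
in a fixed order, so a single integer seed fully determines the draw.

## Inference

Because of the likelihood ridge, the MLE is one-dimensional: the score
`n/λ + Σ log vᵢ − Σ vᵢ^λ log vᵢ` is strictly decreasing in `λ` (its
derivative is `−n/λ² − Σ vᵢ^λ (log vᵢ)² < 0`), so the root is unique.
It is bracketed by geometric expansion from the Power-Function
closed-form start `λ₀ = −n/Σ log vᵢ` and solved with Brent's method on
`[10⁻⁶, 10⁶]`; no sign change in that range is reported as
non-convergence. The observed information in `λ` is
`n/λ² + Σ vᵢ^λ (log vᵢ)²`, always positive; its inverse square root is
the Wald standard error. The 2×2 `(θ, α)` information matrix is also
assembled — its determinant vanishes at any stationary point as a
consequence of the ridge — and is returned with a singularity
diagnostic rather than inverted.

Fixed-partner modes report `α̂ = λ̂/θ₀` (or `θ̂ = λ̂/α₀`); Wald intervals
are built on the `λ` scale and divided through (the map is linear, so no
delta-method correction is needed). The nonparametric bootstrap refits
`λ` on resamples (1,000 by default) and takes percentile intervals; more
than 5% resample-fit failures aborts with a count.

Default support convention when bounds are not given: `a = 0`,
`b = max(sample)` ("zero-to-max"). This is likelihood-proper because the
FPF density is finite at `b`. The "zero-to-inflated-max" alternative,
`b = (1 + 10⁻⁶)·max`, exists for models and users that need the data
strictly interior.

## Competitor models and model selection

Seven comparison distributions are implemented with density, CDF,
log-density, and MLE fitting. Closed forms: Exponential
(`λ̂ = 1/mean`) and Power Function (`θ̂ = n/Σ log((b−a)/(xᵢ−a))`). The
rest use multi-start L-BFGS-B over log-parameters (five log-spaced
starts, bounds `e^(±20)`) followed by a Nelder-Mead polish; the best
log-likelihood wins, with ties broken toward converged results and
smaller parameter norms.

Three source-formula issues are resolved explicitly:

- **Weibull-PF**: the printed CDF is ambiguous between
  `x^θ (b−x)^θ` and `x^θ/(b−x)^θ` inside the exponent. The product
  reading returns to 0 at `b` and is not a CDF; the ratio ("odd")
  reading is used. The product form is exposed as
  `cdf_product_form` for inspection but cannot be fitted.
- **Kumaraswamy-PF and Weibull-PF exponents**: `θ` and `α` enter only
  through `θα`, so the combined exponent is fitted and reported split as
  `θ̂ = α̂ = √(θα)`. Parameter counts for information criteria keep the
  source convention (KwPF 2, WPF 3).
- **Marshall–Olkin-PF**: the standard Marshall–Olkin transform
  `F = u^β/(α + (1−α)u^β)` is used (the printed formula is garbled);
  `α = 1` recovers the plain Power Function.

Information criteria: `AIC = 2k − 2ℓ`, `BIC = k ln n − 2ℓ`,
`CAIC = AIC + 2k(k+1)/(n−k−1)` (the corrected-AIC form, which is what
the published exponential rows satisfy), `HQIC = 2k ln ln n − 2ℓ`. The
FPF is counted at `k = 2` following the source convention, although the
ridge means its effective dimension is 1. Goodness of fit:
KS `D` over order statistics with the asymptotic Kolmogorov p-value
(no estimated-parameter adjustment — the usual practice; treat p-values
as approximate), Cramér–von Mises `W`, Anderson–Darling `A²`.
Likelihood-ratio tests are applied to the nested pairing and Vuong's
normal test on pointwise log-likelihood differences to non-nested
pairs. Strictly, the Power Function is *not* nested in the FPF (no
parameter value removes the exponential tilt exactly); the pairing is
caller-configurable and defaults to treating PF as the nested
comparator, matching common usage for this family.

`compare_models` defaults to the inflated-max bounds rule so competitors
whose densities vanish or diverge at the sample maximum keep finite
likelihoods; all models on a dataset share the same bounds, keeping the
criteria like-for-like. Individual fit failures are recorded in their
table row and never abort the comparison.

## Monte-Carlo harness

Each design cell draws `reps` inverse-transform samples of size `n` at
`λ = αθ`, fits `λ̂` once per replicate, and reports both presentation
columns `α̂ = λ̂/θ_true` and `θ̂ = λ̂/α_true` — the identifiable
(partner-fixed) version of per-parameter bias/MSE/coverage columns.
Coverage is the fraction of 95% Wald intervals containing the truth;
the interval maps linearly to either parameter, so both columns share
one coverage value. Cells are simulated on `(0, 1)`: the shape
estimates' bias, MSE and coverage are invariant to the support because
the likelihood depends only on the normalized `vᵢ`. A master seed
spawns one independent substream per cell, so any cell is reproducible
in isolation. The default design is sizes {10, 50, 100, 500, 1000},
shapes {0.5, 1, 2, 3, 5}², 1,000 replicates.

## Datasets

Three published benchmark lists are embedded in source (they are short
printed tables, not downloads): 76 kidney-infection frailty values
(sum 90.0), 30 repair times, and 100 Fort Collins annual-maximum
precipitation values. Checksums (n, sum, min, max) are asserted at
import. These are real data; everything else the tests consume is
generated programmatically by the package's own samplers.

## What the synthetic data does and does not show

The simulation harness draws exactly from the FPF model — no outliers,
rounding, censoring, or support misspecification. Passing recovery and
coverage tests therefore demonstrates correctness of the estimator and
interval machinery under the model, not robustness to the ways real
bounded lifetime data deviate from it (ties from rounding, unknown
bounds, measurement error). The embedded real datasets exercise the
full comparison pipeline end to end, but with the support convention
`(0, max)`/inflated-max made explicit, since the original analyses'
convention is not recoverable.

## Numerical choices

- Root-finding: Brent with `xtol = 10⁻¹²`; bracketing by factor-4
  geometric expansion from the Power-Function start.
- Quadrature oracles in tests substitute `z = v^λ` to remove the
  integrable endpoint singularity before applying adaptive quadrature.
- `log v` near `v = 1` goes through `log(x − a) − log(b − a)`; CDF and
  quantile use `expm1`/`log1p` forms throughout.
- Degenerate inputs: all-equal samples at the upper bound have no score
  root and raise a clean non-convergence error; all-equal interior
  samples yield a zero-width interval.
- Tables print at 4 dp; JSON output keeps full precision.

## Known limitations

- No censoring, truncation, or covariate structure in the likelihood.
- The support bounds are assumed known (or set by rule); they are not
  estimated, and the `b = max` plug-in slightly biases `λ̂` upward in
  very small samples.
- KS/CvM/AD p-values ignore parameter estimation; for formal testing a
  parametric bootstrap would be needed.
- The `α̂`/`θ̂` split is a reporting convention, not an estimate — only
  `λ̂ = α̂θ̂` is statistically meaningful.
- The MGF series is accurate for moderate `|t|`; very large `|t|`
  exhausts the term ceiling and raises rather than returning an
  inaccurate value.
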