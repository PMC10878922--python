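# Methods

## The model

The package implements a four-parameter heavy-tailed lifetime distribution
built in two layers.  The baseline is the Power Lomax (PLx) law, a Lomax
(Pareto type II) distribution applied to a power of the data:

    G(x; θ, β, λ) = 1 − λ^θ (λ + x^β)^(−θ),   x > 0,

with tail shape θ > 0, power shape β > 0 and scale λ > 0 (λ carries the
units of x^β).  The second layer is an alpha-power transform that maps a
baseline cdf G to

    F(x) = G(x) · α^(G(x)) / α = G(x) · α^(G(x) − 1),

with transform shape α > 0, and density

    f(x) = g(x) · α^(G(x) − 1) · (1 + log(α) · G(x)).

α = 1 returns the baseline exactly (handled as an exact branch, not a
limit).  The family covers decreasing, L-shaped and unimodal densities and
hazards: β < 1 gives a density pole at the origin and an L-shaped hazard,
β = 1 a finite intercept f(0) = θ/(λα), β > 1 a unimodal density with
h(0) = 0.

### Validity region

The transform defines a proper distribution only for α ≥ e^(−1).  For
smaller α the factor 1 + G log(α) becomes negative on part of the support
and the "cdf" overshoots 1 at G* = −1/log(α) (at α = 0.2, F(G*) ≈ 1.14).
`validate_params` enforces α ≥ e^(−1) by default; a permissive mode
downgrades the error to a warning solely so the pathology can be
demonstrated.  The Monte-Carlo study therefore ships configurations with
α ∈ {0.5, 1.5}; configurations below the bound are refused because no
sampler can draw from a non-distribution.

## Numerical design

* **Log-space evaluation throughout.**  The baseline survival is computed as
  `exp(−θ·log1p(x^β/λ))` and the transform weight as
  `exp((G−1)·log α)`.  This keeps the log-density finite for α in the
  thousands (the income-tax fit has α ≈ 1564) and for θ, λ jointly large,
  where the naive `λ^θ(λ+x^β)^(−θ)` cancels catastrophically.
* **Quantiles by two-stage inversion.**  `quantile(p)` first solves the
  scalar equation u·α^u = p·α for the baseline cdf value u ∈ (0,1) — in the
  monotone log form log u + u log α = log p + log α, by 100 steps of
  vectorized bisection (absolute error ~2^(−100)) — then inverts the
  baseline in closed form, x = [λ((1−u)^(−1/θ) − 1)]^(1/β) via `expm1`.
  Root-finding never touches the x scale, which may span many decades.
  The cdf∘quantile round trip holds to 1e−9 across the validity region.
* **Random generation** is inverse-transform sampling of `numpy` Generator
  uniforms: bit-reproducible under a seed, no rejection step.
* **Moment series.**  The r-th raw moment (existing iff r < θβ) is

      μ′_r = θ λ^(r/β) [ (1+log α) Σ_k c_k B(r/β+1, θ(k+1)−r/β)
                         − log α    Σ_k c_k B(r/β+1, θ(k+2)−r/β) ],

  c_k = (−log α)^k/k!.  The (1+log α) weight on the first series is
  essential: dropping it gives a mean of 1.204 instead of 1.768 for the
  (θ,β,λ,α) = (1.5,3,5,1.5) reference row.  Series are truncated adaptively
  (next-term < 1e−12 of the partial sum, cap K = 200) and cross-checked
  against quadrature to 1e−6 relative.  Incomplete moments replace each
  complete beta with the regularized incomplete beta at
  z = (x^β/λ)/(1+x^β/λ); mean residual life is
  m(t) = (μ′₁ − φ₁(t))/S(t) − t.  Central moments are accumulated in
  extended precision when θβ is within 0.5 of the needed order
  (cancellation guard).  Requests with r ≥ θβ raise an existence error
  naming the bound — summary entries degrade to NaN individually.
* **The mgf** exists numerically only for t ≤ 0 (Pareto-type tail); the
  truncated moment series for general t is provided as a formal object and
  documented as such.

## Maximum likelihood

The log-likelihood is Σ log f(x_i) with the safe log-pdf; the analytic
score (∂/∂θ, ∂/∂β, ∂/∂λ, ∂/∂α) is implemented from the chain rule on
log f = log g + (G−1)log α + log(1 + G log α) and verified against central
differences to 1e−5 relative.

Fitting runs on log-parameters (positivity for free, scale-free steps):
L-BFGS-B with the analytic gradient from each start, then a Nelder–Mead
polish of the incumbent.  Multistart defaults: half log-uniform in
[1e−2, 1e2]⁴, half perturbations of a moment-matched PLx pre-fit with
α = 1.5.  α is constrained to [e^(−1)+1e−6, ∞) during fitting.  All
searches are confined to the box [1e−6, 1e6] per parameter: the family
contains boundary limits (a Weibull limit as θ, λ → ∞ jointly, and further
ridges in α) along which some samples' likelihoods creep upward without a
finite optimizer, and the box keeps such fits finite and flagged rather
than divergent.  Standard errors come from the inverse observed information
(central-difference Hessian, relative step ~6e−4); a singular or indefinite
information matrix yields "SEs unavailable" rather than imaginary numbers.

### Identifiability caveat

At moderate n the four parameters are weakly identified: λ and α trade off
along a likelihood ridge, and some samples prefer the Weibull boundary.
Consequences measured here (n = 200, 50 seeded replicates, config
θ=1.5, β=0.7, λ=0.5, α=0.5): all four estimates fall within 3 reported SEs
of truth in ~76% of replicates — not the ~99% a quadratic likelihood would
give — while at least three of four are covered in 96%.  The power shape β
is the best-identified parameter; its absolute bias and MSE shrink
monotonically through n = 30, 80, 200 in the Monte-Carlo study (500
replicates per size, seeded substreams, AE/AB/MSE layout).

### Reference fits

On the bundled bladder-cancer remission times (n = 128) the four-parameter
fit has an interior optimum at (θ, β, λ, α) = (2.952, 1.012, 9.630, 7.504)
with NLL 409.4004 — these are exactly the four published point estimates of
this model on these data (whose printed row labels are permuted), while the
published −ℓ of 407.40 is inconsistent with them and with the published
AIC/BIC of that row; the package computes AIC/BIC from its own NLL.  On the
income-tax data (n = 59) the likelihood is a ridge in α (infimum ≈ 188.45 as
α → ∞); at the published estimates it evaluates to 188.67, not the published
187.66.  The Lomax and Power Lomax rows of both published tables, and both
Marshall–Olkin rows on the bladder data, reproduce to 0.05.

## Competitor models and model comparison

Lomax, Power Lomax and their Marshall–Olkin tilts use the tilt
F_MO = F₀/(a + (1−a)F₀); the orientation was fixed by requiring the
published fit values to reproduce at the published estimates (they do, to
0.05, for the seven internally consistent rows).  a = 1 reduces to the
baseline identically.

Goodness of fit uses the classical EDF statistics (two-sided KS,
Anderson–Darling, Cramér–von Mises) computed from their defining order-
statistic sums with F clipped away from {0,1} by 1e−12; KS and CVM
p-values come from the standard asymptotic null distributions (scipy), the
AD p-value from a standard asymptotic approximation.  All p-values are
labeled approximate because the cdf's parameters are estimated from the
same sample.  The comparison table recomputes AIC = 2k + 2·NLL and
BIC = k·log n + 2·NLL from its own NLLs, so the report invariant holds by
construction.  Plot-ready data (TTT transform, PP pairs, fitted
pdf/cdf/survival curves, boxplot summaries) are emitted as coordinate
tables; figure styling is out of scope.

On the bladder data the four-parameter model ranks first on every
criterion.  On the income data three models sit on overlapping boundary
ridges within 0.6 nats of each other (MOPLx 188.55, NAPTPLx 188.58, PLx
189.16 at box-bounded optima); rankings there are not robust and the
package reports them as computed.

## Bayesian inference

Independent Gamma(a_i, b_i) priors (shape/rate) on all four parameters,
defaults a_i = b_i = 0.1 — vague but proper; the hyperparameters behind the
published posterior summaries are not stated anywhere, so those numbers are
not reproducible and the package targets recovery properties instead.  The
sampler is random-walk Metropolis on log-parameters with the log-scale
Jacobian included in the acceptance ratio.  Per-parameter proposal scales
adapt every 100 burn-in iterations toward 20–40% acceptance and are frozen
afterwards, so the kept chain is a valid Metropolis sampler.  Desk-scale
defaults 50,000/5,000/10 (iterations/burn-in/thinning); larger,
publication-scale settings are plain arguments.  HPD intervals are the
shortest window containing ⌈mass·N⌉ sorted draws (exhaustive window scan);
the Geweke diagnostic compares the first 10% and last 50% window means with
spectral-density-at-zero standard errors from a Bartlett lag window
(lag ≈ √n), is ~N(0,1) on stationary chains (92–97% of i.i.d. chains fall
within ±1.96 over 200 seeds), and returns a flagged 0 on constant chains.

## What the synthetic-data generator does and does not show

Synthetic samples are exact inverse-transform draws from the model itself:
i.i.d., fully observed, no censoring, no covariates, no measurement
rounding.  Passing recovery tests therefore demonstrate correctness of the
sampling–fitting–summarizing loop and finite-sample estimator behavior
under the model, not robustness to the misspecification, censoring or
heaping that real remission-time data may carry.  The bundled clinical and
economic datasets are kept verbatim as published (128 and 59 observations,
checksummed) so results remain comparable with the literature on them.

## Problem sizes

Defaults are desk-scale, chosen so the full study re-runs in minutes on one
core: 500 Monte-Carlo replicates per sample size (the published study used
10,000 — available by setting `n_reps`), 40-start reference fits, 4-start
fits inside the replication loop, 50,000-iteration reference chains and
20,000-iteration chains inside coverage loops.  All stochastic entry points
take a seed and are bit-reproducible.

## Known limitations

* No censoring or truncation support anywhere in the likelihood.
* Wald standard errors degrade under the λ–α ridge (see the
  identifiability caveat); profile or bootstrap intervals are not provided.
* The mgf series for t > 0 is formal; the distribution has no finite
  exponential moments.
* EDF-statistic p-values ignore parameter estimation (the field's usual
  reporting convention, flagged in the output).
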