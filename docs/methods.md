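# Methods

## Model

`ratewalk` models a univariate continuous trait on a fixed, rooted,
time-calibrated phylogeny. The trait evolves by Brownian motion whose
rate σ² is itself stochastic: ln σ² follows Brownian motion with drift
μ (the **trend**, per unit time) and infinitesimal variance σ²_σ (the
**rate variance**, per unit time). Geometric Brownian motion keeps rates
positive and makes them vary multiplicatively, which matches how rates of
phenotypic evolution are usually conceived. Negative trends give gradually
declining rates (early bursts), positive trends late bursts, and rate
variance 0 collapses the model exactly onto the classical
exponential-rate-change (EB/BM/LB) family.

Because the marginal likelihood of the trait data under a true GBM rate
process has no closed form, inference conditions on **branchwise rates**
σ̄²_k — the time-average of σ² along branch k — and uses a multivariate
log-normal approximation for their joint distribution:

    ln σ̄² ≈ β + γ,   γ ~ MVN(0, σ²_σ · D)

* β_k = ln σ₀² + ln[(e^{μτ₂} − e^{μτ₁}) / (μ t_k)] is the log of the
  time-averaged deterministic trend over the branch interval
  [τ₁, τ₂] (time 0 at the root), with ln σ₀² the log rate at the root.
* D_ij sums branch lengths over branches ancestral to both i and j
  (each branch ancestral to itself) with corrections for within-branch
  averaging: −2t_i/3 on the diagonal and −t_i/2 when i is ancestral to j.
  A root branch of length t then has variance t/3, the variance of the
  time-average of a standard Brownian path — this is what forces the
  self-inclusion convention in the ancestry function, which the tests pin
  down against Monte-Carlo simulation of the underlying paths.

γ is the distribution of *geometric* average rates; the arithmetic
averages that actually govern trait variance differ from it by a small
Jensen gap. The test suite quantifies this on 10-tip trees at rate
variance 3 and 6: geometric-average log rates match (β, σ²_σ D) to
Monte-Carlo precision, and the arithmetic-average log rates deviate in
mean by ≲ 0.12·σ²_σ — the approximation error the model accepts by
design.

Conditional on branchwise rates, tip trait values are multivariate normal
with covariance C_ij = Σ_{k ∈ anc(i,j)} σ̄²_k t_k ("squashing and
stretching" of branch lengths).

## Likelihood

The trait likelihood is computed by Felsenstein's pruning algorithm with
the root trait value marginalized analytically — implemented as the
contrast (REML) likelihood, equivalent to an improper flat prior on the
root state. The root state is therefore never sampled. A dense
generalized-least-squares implementation (`dense_reml_loglik`) exists
solely as an independent oracle; the test suite requires agreement to
1e−8 on random trees.

Tips with m raw measurements enter as their mean with variance σ²_y/m,
plus the density of the m−1 within-tip contrasts
N(y_{k+1} − ȳ_{1:k}; 0, σ²_y (k+1)/k). Tips with no measurements are
*data-deficient* (undefined mean, infinite variance): they propagate
through the pruning pass without contributing contrasts and provably do
not change the likelihood. One shared free tip-error variance covers all
tips without a fixed variance; per-tip fixed variances (e.g. squared
standard errors of species means) are honored as normal priors on the tip
value.

Multifurcations are binarized with zero-length pseudo-branches (grouping
children left-to-right; the likelihood is invariant to the grouping).
Pseudo-branches receive no rate parameter and are excluded from β, D and
the latent vector.

## Posterior and sampling

Sampling uses the uncentered parameterization: latent z ~ N(0, I) with
ln σ̄² = σ_σ L z + β, where L is the (jittered, if necessary) Cholesky
factor of D. Unconstrained coordinates are [μ, ln σ₀², ln σ_σ,
(ln σ²_y), z]; half-Cauchy priors on the rate variance (scale 5/T) and
tip-error variance (scale σ²_raw/2) pick up explicit log-scale Jacobians.
Remaining defaults: trend ~ N(0, (10/T)²) (a 10/T trend is an
e¹⁰ ≈ 20,000-fold rate change over the tree height T — deliberately
liberal), ln σ₀² ~ N(ln(σ²_raw/T), 10²) with σ²_raw the pooled variance
of the raw measurements.

No gradient-based PPL is part of the dependency stack, so the package
carries its own machinery:

* a hand-written reverse-mode gradient through the pruning recursion
  (exact; checked against central finite differences at 1e−5 relative
  tolerance), jitted with numba and falling back to pure Python;
* a multinomial no-U-turn sampler with dual-averaging step-size
  adaptation (target acceptance 0.9, divergence threshold 1000 nats,
  max tree depth 10) and a diagonal mass matrix estimated in expanding
  warmup windows. The sampler is validated on correlated Gaussians,
  funnel geometry, and — most stringently — prior-only runs of the real
  model, which must reproduce all four prior distributions
  (Kolmogorov–Smirnov checks).

Chains start at the Brownian backbone (z = 0, μ = 0, ln σ₀² at its prior
location, small σ_σ) with small jitter; per-chain seeds derive
deterministically from one master seed. Convergence is summarized by
rank-normalized split R̂ and bulk ESS (via ArviZ); defaults flag R̂ > 1.05
or ESS < 400 with a warning to lengthen chains, never a silent failure.

## Hypothesis testing

* **Trend**: PP(μ > 0), read against 0.025/0.975 (two-tailed at 0.05).
* **Rate heterogeneity**: Savage–Dickey ratio — posterior density of the
  rate variance at 0 over the prior density 2/(π·5/T); ratios ≤ 1/3 count
  as substantial evidence. The boundary density is estimated by
  reflecting the draws about 0 and evaluating a Gaussian KDE whose
  bandwidth uses a robust (IQR-based) Silverman rule after clipping the
  top 1% — heavy half-Cauchy-like tails otherwise inflate the bandwidth.
  A histogram boundary estimator is the fallback, with a warning. The
  estimator is validated on draws from the prior itself (ratio ≈ 1).
* **Branch anomalies**: branchwise rates are detrended by subtracting the
  time-varying part of β (the ln σ₀² level is retained so detrended
  values stay log rates — "subtracting β" verbatim would leave residuals,
  not rates); the background rate is the branch-length-weighted geometric
  mean of detrended rates (arithmetic available per option, as are
  untransformed rates and clade-restricted backgrounds), and
  PP(deviation > 0) per branch is read against 0.025/0.975. No
  multiple-testing correction is applied across branches; the calls are
  screening heuristics, not formal tests.
* **Fold changes**: the per-unit-time rate fold change is
  exp(μ + σ_σ X), X ~ N(0,1): its median is exp(μ) (median-rate trend)
  while the *average* rate trends as μ + σ²_σ/2 — with strong
  heterogeneity most lineages can slow down while the clade-average rate
  rises.

## Synthetic data

The generator reproduces the simulation-study design: pure-birth trees
rescaled to height 1 (the Yule birth rate is irrelevant after rescaling
and fixed at 1; the process is conditioned on n tips with an Exp(n)
tail after the last split), trait and log rate 0 at the root, rate
variance in {0, 3, 6} × trend in {−4, 0, 4} × tree sizes {50, 100, 200}
× 10 replicates (270 cells), one error-free observation per tip.
Rates can be drawn either exactly from the log-normal approximation or
from fine-grained GBM (per-branch Euler steps with exact Gaussian
increments of the log rate; trapezoid averaging of the rate and log-rate
paths, ≥ 20 steps per branch, 50 by default). What the generator does
*not* emulate: non-ultrametric sampling, fossil tips, correlated
multivariate traits, non-Gaussian measurement error, or model
misspecification of any kind — passing calibration tests therefore
demonstrates internal consistency (simulation-based calibration), not
robustness to real-data violations.

## Numerical choices

* β uses the stable form ln σ₀² + μτ₁ + f(μt), f(a) = ln((eᵃ−1)/a), with
  a second-order series below |a| < 1e−6; zero-length branches take the
  point value at τ₁.
* Cholesky of D retries with jitter 1e−10·max diag, escalating tenfold,
  three times.
* Per-node variance sums in the pruning pass are floored at
  1e−12·σ²_raw (zero-length cherries); gradient flow through a floored
  node treats the floor as constant.
* Tied replicate measurements with σ²_y = 0 are treated as a point mass
  (partial likelihood 1); conflicting replicates with σ²_y = 0 yield
  −∞ with a warning.

## Problem sizes and what the checks show

The calibration studies shipped with the package are scaled-down
replicates of the full design, sized for Monte-Carlo precision: coverage
of the 95% intervals for trend and rate variance is estimated from 20
replicates (36-tip trees, rate variance 3, no trend; binomial standard
error ≈ 3.4 points around the nominal 95%), and the branchwise-rate
shrinkage slope is averaged over 18 fits spanning all six
heterogeneous-rate scenarios on 50-tip trees, with 2 chains × 1000
iterations per fit. The shrinkage statistic varies strongly by scenario:
trend-dominated scenarios regress near slope 0.9–1.0 while the
no-trend/moderate-heterogeneity corner alone sits near 0.55 — only the
scenario-averaged value (~0.7–0.8, reflecting prior-induced shrinkage of
branch-level estimates toward the background rate) is a stable summary.
Posterior medians of branchwise rates shrink by construction; rate
*variance* estimates are approximately unbiased, so joint draws remain as
dispersed as the truth.

## Known limitations

* The log-normal approximation degrades on very long branches at high
  rate variance (the Jensen gap grows with σ²_σ t).
* The Savage–Dickey boundary estimate is a density estimate; with few
  draws (< 1000) it warns and should not be trusted to fine precision.
* Trait data at internal nodes (fossils) and posterior sampling of
  ancestral/tip trait states are not implemented.
* Maximum-likelihood EB/BM comparison via information criteria is out of
  scope; the constrained-model fit covers that family in the Bayesian
  setting.
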