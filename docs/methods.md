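# Methods

## Model

`bernexp` fits a joint model for a binary longitudinal outcome and the
elapsed time between visits. For subject *i* (covariates *xᵢ*, first entry
an intercept 1) observed at visits *k = 1..nᵢ*:

* first visit: `y_i1 ~ Bernoulli(μ_i1)`, `logit(μ_i1) = xᵢ'α`;
* later visits: `y_ik ~ Bernoulli(μ_ik)`,
  `logit(μ_ik) = xᵢ'α + ϑ t_ik + ψ y_ik−1`;
* later gap times: `t_ik ~ Exponential(rate = exp(ξ + γ y_ik−1))`.

Assumptions worth stating explicitly:

* **One-step dependency.** The current outcome depends on the past only
  through the immediately preceding outcome and the current gap time.
* **Gap times, not cumulative times.** `t_ik` is the increment since the
  previous visit. Readers of cumulative-time data must difference first.
* **Subject-level covariates.** *xᵢ* is time-invariant; time-varying
  covariates are out of scope.
* **No first-gap density.** The likelihood contains Bernoulli terms for all
  visits but exponential terms only for `k ≥ 2`; `t_i1` enters neither the
  mean structure (the first logit has no time term) nor the density. The
  *simulator* nevertheless draws `t_i1 ~ Exp(exp(ξ))` so generated panels
  have complete time columns; the fitter simply ignores that column's first
  entry. This asymmetry is intentional.
* **No truncation.** Follow-up horizons are treated as a validation bound
  (`PanelDataset(tau=...)`, default +∞), never as a truncation of the
  exponential density.
* **Noninformative censoring** is assumed, not modelled.

## Priors

Three bundles, addressed by the stable names `informative`,
`noninformative`, `jeffreys`:

| scheme | α | ψ, ϑ, ξ, γ |
|---|---|---|
| informative (simulation) | N(0.6·1, 5·I) | ϑ~N(0.2, 0.3), ψ~N(0.3, 0.4), ξ~N(0.3, 0.2), γ~N(1, 1.5) |
| informative (recurrence application) | N(0.4·1, 4·I) | ϑ~N(0.5, 0.5), ψ~N(0.2, 0.2), ξ~N(2.0, 0.2), γ~N(0.2, 0.1) |
| noninformative | N(0, 10⁸·I) | each N(0, 10⁸) |
| jeffreys | ∝ \|X̃'WX̃\|^½ | each N(0, 10⁸) |

Second arguments are variances throughout. The Gaussian scale φ is fixed at
1 and never sampled. In the simulation-informative bundle the fourth
visit-side hyperparameter slot is assigned to γ; the source material labels
that slot with a symbol that corresponds to no likelihood parameter, and
four visit-side slots exist for four visit-side parameters.

The Jeffreys prior for α is `|X̃'WX̃|^{1/2}` where X̃ stacks one covariate
row per visit and `W = diag(μ_ik(1−μ_ik))` is evaluated at the *full* joint
mean — i.e. conditionally on the current (ψ, ϑ) and the observed
(t, y_prev); consequently it also enters the acceptance ratio of ψ and ϑ
updates. It is improper and data-dependent; posterior propriety is assumed,
not proven. A singular information matrix (collinear covariates, saturated
means) yields a log prior of −∞ with a warning rather than a crash.

## Sampler

The full conditionals are non-conjugate, so each scalar parameter is
updated in turn (`α_1..α_p, ψ, ϑ, ξ, γ`) by a Gaussian random-walk
Metropolis step — Metropolis-within-Gibbs. Implementation points:

* **Adaptation.** During burn-in, proposal scales adapt in batches of 50
  sweeps: after each batch the log-scale moves by ±min(0.1, 1/√batch)
  toward a 0.44 acceptance rate (the univariate random-walk optimum), then
  freezes, so the retained chain is Markov. Post-burn-in acceptance rates
  outside [0.05, 0.95] raise a warning.
* **Thinning rule.** Post-burn-in sweep *j* (1-based) is kept iff
  `(j−1) mod thin == 0`, giving `ceil((n_iter − burn_in)/thin)` draws —
  6667 under the defaults 30000/10000/3.
* **Initial values** default to the Gaussian prior means (zeros under the
  vague and Jeffreys bundles) and must have finite log posterior.
* **Caching.** The target is split into a Bernoulli block (α, ψ, ϑ) and an
  exponential block (ξ, γ); a coordinate update recomputes only its block.
  Per-subject partial likelihood sums are reduced in sorted order, making
  the log-likelihood — and hence Gaussian-scheme chains — exactly invariant
  under subject relabelling. The Jeffreys determinant uses a BLAS matmul,
  so under that scheme invariance holds only to floating-point noise.
* **Determinism.** All randomness flows from `MCMCConfig.seed` through one
  PCG64 generator; identical configs give bitwise-identical draws.

Summaries are the sample mean, sd (n−1 denominator) and equal-tailed
2.5%/97.5% empirical quantiles with linear (type-7) interpolation — not HPD
intervals. DIC is `Dhat + 2·pD` with `pD = Dbar − Dhat`, `Dbar` the mean
deviance over retained draws and `Dhat` the deviance at the column-mean
parameter vector.

## Convergence diagnostics

Heidelberger–Welch, two stages per parameter chain:

1. **Stationarity.** Cramér–von Mises statistic of the standardized
   Brownian bridge of cumulative sums, with the long-run variance S(0)
   estimated from the second half of the chain by overlapping batch means
   (batch length ⌊√N⌋). P-values come from an embedded table of the
   asymptotic CvM distribution (Bessel-series values, log-linear
   interpolation of the survival function). On rejection at the 5% level
   the first 10% of the chain is discarded and the test repeated, up to
   50%. Zero-variance chains pass by convention with p-value 1.
2. **Halfwidth.** On the stationary portion,
   `halfwidth = z_0.975 · sqrt(S(0)/N)` must be less than ε = 0.1 of the
   absolute mean. A posterior mean of exactly zero gives ratio +∞ and a
   flagged failure.

The halfwidth criterion is intrinsically scale-free but *location*-bound: a
parameter whose true posterior mean is near zero (in the canonical study
truth, ξ = 0.01 and α₄ = 0.1) can fail it with an arbitrarily well-mixed
chain. Published all-pass diagnostic tables at such truths imply some other
convention for near-zero means that we could not recover; this package
keeps the strict ratio rule and documents the consequence rather than
special-casing near-zero means.

## Synthetic-data generator

`generate_covariates` draws, per subject: an intercept, two independent
uniform 3-level factors (reference level dropped, 2 dummies each) and two
standard-normal continuous covariates — 7 columns. `simulate_panel` then
draws outcomes and gaps sequentially from the model. The canonical truth is
α = (0.4, 0.2, 0.3, 0.1, 0.3, 0.4, 0.9), ψ = 0.8, ϑ = 0.12, ξ = 0.01, and
γ = 0.4; γ's published value is ambiguous, so it is an explicit argument
with this documented default. The study grid crosses sample sizes
{18, 54, 180} with visit patterns balanced(10), unbalanced(5 & 3) and
unbalanced(20 & 6); in unbalanced cells the first half of subjects by index
takes the longer schedule. Cell observation totals: 180, 72, 234, 540, 216,
702, 1800, 720, 2340.

What the generator does *not* emulate: dropout and informative censoring,
time-varying covariates, measurement error in visit times, and any
between-subject heterogeneity beyond the covariates (no random effects).
Passing recovery tests on these panels therefore demonstrates internal
consistency of the estimation machinery — not robustness to the ways real
panel data violate the model.

## Problem sizes used in the checks

The published study used 1000 replicates of 30,000-iteration chains per
cell; the packaged checks keep the full chain length where a single fit is
probed and scale replicate counts down as each check's purpose allows:
parameter-recovery coverage uses 50 replicates at n = 180 with
6000/2000-iteration chains, the CI-width comparison 20 replicates per
sample size, the DIC pattern comparison 3 replicates per cell with
4000/1000-iteration chains (DIC cell means stabilise well before that), and
the acceptance script 3 replicates per cell at the full 30000/10000/3
settings. These sizes are the package's own defaults for its test
conditions; every driver accepts larger values.

## Known limitations

* Random-walk Metropolis mixes slowly for strongly correlated posteriors;
  n_iter should be raised for p much beyond ~10.
* The Jeffreys posterior's propriety is assumed; with tiny panels or
  separated outcomes the sampler can stall at −∞ prior regions (reported as
  a hard error at initialisation).
* DIC is the only model-comparison criterion offered, mirroring the
  method's reporting conventions; WAIC/LOO are deliberately out of scope.
* Recurrence tables are capped at four visits per subject; deeper histories
  are rejected rather than truncated. Zero gap times are floored at 0.01
  with a warning, since the exponential density requires t > 0.
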