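# Methods

## Setting

Observed data x = (x₁, …, xₙ) are modeled as i.i.d. draws from a parametric
family f(·|θ) with a proper prior π(θ) — the *statistical* model.  To study
a GOF p-value frequentistly we also need the *probabilistic* model that
actually generated the data: the same likelihood with a prior π₀ (possibly
a point mass).  A p-value is *calibrated* when, with x resampled from the
probabilistic model, its distribution is U(0, 1).

Three conjugate families are implemented, so every posterior is closed
form and no MCMC is needed:

| family | likelihood | prior | posterior update |
| --- | --- | --- | --- |
| poisson | Poisson(λ) | Gamma(a, b) (shape/rate) | (a+Σx, b+n) |
| bernoulli | Bernoulli(p) | Beta(a, b) | (a+Σx, b+n−Σx) |
| normal | Normal(μ, σ²) | normal-inverse-gamma (μ₀, κ₀, a₀, b₀) | standard NIG update |

The normal prior is the fully conjugate NIG form — σ² ~ InvGamma(a₀, b₀),
μ | σ² ~ Normal(μ₀, σ²/κ₀) — chosen over a semi-conjugate independent-prior
form precisely so that posteriors stay closed form.

## The p-value engines

All engines estimate p = Pr(d(X, θ) ≥ d(x, θ)) under a reference scheme,
with ties randomized: a single u ~ U(0, 1) per p-value allocates the tied
replicates, making the p-value exactly uniform even for discrete-valued
discrepancies.  Equality of float discrepancies is declared at relative
tolerance 1e−12 (exactly, for integer-valued statistics).

* **spp** — one θ̃ from the posterior; K replicate datasets from f(·|θ̃).
  Exactly uniform under matched priors for every discrepancy; asymptotically
  uniform otherwise (posterior consistency concentrates θ̃ at the true
  value).
* **nspp** — spp after the *normalization* transform: yᵢ =
  Φ⁻¹(F^rand_θ̃(xᵢ, uᵢ)) with the randomized CDF F^rand(x, u) =
  F(x−1) + u·(F(x) − F(x−1)) for discrete families (F(x) itself for
  continuous ones).  Model-distributed data map to exact i.i.d. N(0, 1), so
  any statistic of y is pivotal and the p-value is uniform at every n, not
  just asymptotically.  Replicates drawn at θ̃ and normalized with θ̃ are
  exact standard normal samples and are simulated as such.
* **ppost** — posterior predictive: a fresh θ_k per replicate,
  d(X_k, θ_k) compared with d(x, θ_k) pairwise.  Conservative when the
  discrepancy's mean depends on θ.
* **plugml / halfml** — parametric bootstrap at the full-data MLE or at the
  MLE of a uniformly random ⌊n/2⌋ half-sample (the half-sample version
  restores asymptotic uniformity for EDF-type statistics).  A boundary MLE
  (Poisson mean 0, Bernoulli proportion 0 or 1) raises an error directing
  users to the Bayesian engines; a boundary *half-sample* only (interior
  full-data MLE) triggers a subset redraw, since random half-samples of
  sparse count data legitimately hit the boundary.
* **prior** — prior predictive (pairwise, as ppost); strongly prior
  -dependent, included as a comparator.
* **freqspp** — SPP with the posterior draw replaced by a frequentist draw:
  log λ ~ Normal(log λ̂, 1/Σx) for the Poisson family (the asymptotic
  distribution of the intercept of a log-link GLM).

Monte Carlo estimation: after counting a* = #{d_rep > d_obs} + u·#{ties}
among K replicates (K defaults to 5000), the reported p-value is one draw
from Beta(a*+1, K−a*+1) — the posterior of the underlying p-value under a
uniform prior.  Unlike the classical count/K estimate, pooling beta-draw
p-values over datasets reproduces the distribution of the exact p-value
even at small K; the suite demonstrates the contrast at K = 100.  The
classical estimate (#{d_rep ≥ d_obs}/K) remains available as
`estimator="naive"` for that diagnostic.

Because θ̃ is random, the SPP can differ across runs on the same data;
`spp_quantile_band` reports the empirical q-quantile of M independent-θ̃
SPPs, holding the observation-normalizing uniforms fixed across draws so
that repeated analyses of one dataset are comparable.

## Discrepancy registry

Raw-scale: mean, variance (denominator n−1), maximum, centered mean/variance
(sample moment minus the model moment at θ), log-likelihood.  Normalized
-scale: mean, variance, maximum, skewness and kurtosis (biased moment
estimators; kurtosis raw, not excess — only the induced ordering matters
for p-values), and Zhang's Z_A,

    Z_A = −Σᵢ [ log U₍ᵢ₎ / (n−i+0.5) + log(1−U₍ᵢ₎) / (i−0.5) ],

on the ascending-sorted uniformized values U₍ᵢ₎ = Φ(y₍ᵢ₎).  Statistic
kernels operate on the last axis of (K, n) arrays so batch studies are
vectorized end to end.

## Synthetic study design

`scenarios` generates (probabilistic model, statistical model, dataset)
triples; it is the package's data source — no external data are used.  The
base (scenario-1) prior has a fixed center and a per-dataset random
dispersion, emulating a population of analyses:

* poisson: mean 1; index of dispersion ~ LogNormal(0, 1);
* bernoulli: mean 0.5; concentration a+b ~ LogNormal(log 4, 1);
* normal: μ₀ = 0, σ² ~ InvGamma(3, 2); marginal prior sd of μ ~
  LogNormal(0, 1) (via κ₀).

Scenario 2 multiplies the statistical-prior sd by a sharpness factor
μ_σ0 ~ LogNormal(0, 1) at fixed center (Gamma and Beta shapes scaled by
1/μ_σ0²; κ₀ likewise).  Scenario 3 additionally off-centers the
statistical prior by θ₀ ~ LogNormal(0, 0.5) on the natural scale: the
Poisson prior mean is multiplied by θ₀ at fixed variance, the Bernoulli
log-odds shift by log θ₀ at fixed concentration, the normal location
shifts by log θ₀ prior-sd units.  Results are stratified by μ_σ0 bins
(0.40 / 1.01 / 2.59) and |log θ₀| bins (0.14 / 0.28 / 0.47 / 1.73).
Scenario 4 keeps the scenario-1 statistical prior but generates data at a
*fixed* parameter: a Dirac π₀ at the statistical-prior mean.

Sample sizes follow a two-component law on {20, …, 1000}: with probability
0.7 uniform on the multiples of 10 in [20, 200], otherwise uniform on the
multiples of 100 in [300, 1000] — small studies dominate, and the rounding
makes strata reproducible.  The rounded values are drawn directly so the
small-study mass is exactly 0.7.

**Power study.**  The alternative is the Polya (beta-binomial) distribution
on {0..m}: pᵢ ~ Beta(α, β) per observation, Xᵢ ~ Binomial(m, pᵢ), with
(α, β) solved in closed form so mean and variance match the Poisson being
tested (feasible iff the variance exceeds the binomial floor m·p·(1−p)).
The power-study Poisson mean defaults to 2.5 — its own setting, distinct
from the calibration scenarios' mean 1, because with mean 1 a
moment-matched beta-binomial on {0..5} is practically indistinguishable
from the Poisson (every engine's rejection rate sits at the nominal level)
and the study would measure nothing.  At mean 2.5 the bounded support
genuinely truncates the upper tail and the characteristic engine ordering
emerges.  Sample sizes cycle deterministically through the configured grid
(default {20, 50}; the CLI default grid extends to 80).

**What the generator does not emulate.**  Real data are rarely i.i.d.
scalar draws from a one-parameter family: no covariates, no hierarchy, no
dependence, no measurement error.  Passing calibration here shows the
engines are correct *as p-values* under their stated assumptions; it says
nothing about the adequacy of any particular scientific model.

## Diagnostics

Batches of p-values are judged by (i) a one-sample KS test against
U(0, 1) (asymptotic p-value; study uses have N ≥ 2000); (ii) the frequency
in the two-sided `level` extremities — below level/2 or above 1 − level/2 —
with a *randomized* two-sided binomial test (2·min(V, 1−V) of the
randomized binomial PIT V, exactly uniform under the null despite the
discrete count); and (iii) a negligibility band code from the
Beta(count+1, N−count+1) posterior of the tail proportion: at the 5% level
`zero_zero`/`zero` when the 95% credible interval lies inside
(0.04, 0.06)/(0.03, 0.07), `plus`/`plus_plus` when it lies above
0.06/0.07, `minus`/`minus_minus` mirrored below, `none` otherwise; all
cutoffs divide by 5 at the 1% level.  The two-sided reading of
"extremities" is deliberate: for most registry statistics both a too-large
and a too-small discrepancy signal misfit.  Power against an alternative
is the extremity frequency at the chosen level.

For tiny Bernoulli problems `exact.spp_exact_cdf_bernoulli` computes the
SPP's distribution deterministically — enumeration over dataset sums
(beta-binomial weights), midpoint-rule quadrature over the Beta posterior,
and closed-form integration over the tie draw — providing a Monte
-Carlo-free uniformity reference that the test suite checks to < 0.01
sup-deviation at n = 1, 2, 3.

## Numerical and design notes

* Randomized-CDF values of exactly 0 or 1 (float underflow, e.g. a Beta
  draw returning p = 1.0) are clamped before Φ⁻¹ with a warning.
* Gamma variates with minuscule shape parameters (ultra-sharp scenario
  priors scaled by 1/μ_σ0²) can underflow to 0.0; they are clamped to the
  smallest positive float so parameters stay inside the open space.
* Normal-family MLE variance uses denominator m (the MLE), not m−1; the
  plain "variance" statistic uses n−1.
* Batch runs derive all randomness from a master seed via spawned child
  streams, one per replicate split again per engine: outputs are
  byte-identical across runs, datasets are shared across engines and
  discrepancies within a replicate, and any single replicate can be
  reproduced in isolation.  Engines evaluating several discrepancies share
  the reference parameter and replicates (each p-value's marginal law is
  unchanged; only the MC noise is shared).
* Study sizes in the shipped tests are scaled to desk hardware: 2000
  datasets (matched-prior calibration, all families), 5000–20000
  (mismatched-prior strata), 5000 per cell (conservativeness and power),
  K = 1000; the full-scale configuration (10⁵ datasets, K = 5000) is
  available through the same configs.

## Known limitations

* Only the three conjugate i.i.d. families; no regression structure,
  hierarchy, or generic MCMC.  `freqspp` covers the Poisson family only.
* The posterior predictive engine's power deficit is reproduced for the
  maximum (raw and normalized scales) and Z_A statistics; for skewness and
  kurtosis on normalized data — statistics that are nearly pivotal, so the
  observed discrepancy barely varies across posterior draws — we measure
  no systematic spp/halfml advantage under the moment-matched Polya
  alternative at any feasible Poisson mean.
* Partial/conditional predictive p-values and post-processed (calibrated)
  posterior predictive p-values are out of scope; user-defined
  discrepancies beyond the registry hook are not supported.
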