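# Methods

## Model and estimation

The package uses the mean–precision parametrization of the beta law:
`f(y; μ, φ)` with mean μ ∈ (0,1) and precision φ > 0, variance
μ(1−μ)/(1+φ).  The log-likelihood depends on the data only through
`y* = log(y/(1−y))` and `y† = log(1−y)`, with expectations
`μ* = ψ(μφ) − ψ((1−μ)φ)` and `μ† = ψ((1−μ)φ) − ψ(φ)` (ψ the digamma
function).  The per-observation score is `(φ(y*−μ*), μ(y*−μ*)+(y†−μ†))`
and the Fisher information has entries `B_μμ = φ²w`, `B_μφ = c`,
`B_φφ = μc/φ + (1−μ)ψ′((1−μ)φ) − ψ′(φ)` with
`w = ψ′(μφ) + ψ′((1−μ)φ)` and `c = φ(μw − ψ′((1−μ)φ))`.

Maximum likelihood runs in unconstrained coordinates
`(logit μ, log φ)` so no box constraints are needed.  `fit_mle` is BFGS
with the analytic chain-rule gradient started from the method-of-moments
values `(ȳ, ȳ(1−ȳ)/V̂ − 1)` (V̂ with the n−1 denominator; the precision
start is clipped into [1e−2, 1e6] to survive near-degenerate samples),
followed by a Fisher-scoring polish.  The convergence criterion is a
sup-norm ≤ 1e−8 on the gradient of the **mean** log-likelihood (per
observation), which keeps the tolerance meaningful at every sample size;
an absolute tolerance on the total gradient would be unattainable in
double precision for very large n.  Because the likelihood is a function
of three sufficient statistics (n, Σy*, Σy†), the bootstrap and Monte
Carlo paths use `_fit_many`, a vectorised Fisher-scoring solver over
batches of sufficient-statistic triples: each iteration solves the 2×2
expected-information system with backtracking on the mean log-likelihood
(acceptance allows a rounding-level decrease so the line search cannot
stall at the optimum).  Tests verify that it reaches the same stationary
points as `fit_mle` to 1e−6 relative.  Refits that end on the internal
`log φ` cap (φ ≈ 6.6e7) are flagged non-converged.

Beta variates come from the generator's gamma-ratio construction.  Only
distributional equality matters anywhere in the package, so the choice of
sampling algorithm (versus, e.g., acceptance–rejection) is immaterial;
draws that round to a boundary in floating point are nudged into the open
interval.

## The restriction vector and its covariance estimators

The misspecification tests are built on
`d(θ; y) = vech(Hessian + score·scoreᵀ)` with components

- `d1 = φ²[(y*−μ*)² − w]`
- `d2 = (y*−μ*) − c + φ(y*−μ*)[μ(y*−μ*) + (y†−μ†)]`
- `d3 = −μc/φ − (1−μ)ψ′((1−μ)φ) + ψ′(φ) + [μ(y*−μ*) + (y†−μ†)]²`

and their sample average `Dn`.  By default q = 2 restrictions (d1, d2)
are tested: the third component is numerically near-degenerate, and
including it makes the covariance estimates nearly singular.  q = 3
remains available behind an explicit argument; covariance estimates with
condition number above 1e12 raise an error rather than being silently
pseudo-inverted.

The analytic Jacobian ∇Dn is implemented from closed-form partials of
(μ*, μ†, w, c).  One partial of d3 with respect to μ is written here with
the μ-derivatives of μ* and μ† in its product term — the form required by
differentiation and confirmed against a finite-difference Jacobian oracle
in the tests.  This only matters at q = 3.

Three covariance estimators for √n·Dn(θ̂) are provided:

- `Vn1` (White): residuals `d_t − ∇Dn·An⁻¹·score_t`, An the sample
  average Hessian;
- `Vn2` (Chesher–Lancaster): residuals `d_t + Ln·Bn⁻¹·score_t`, with
  `Ln = −(1/n)Σ d_t scoreᵀ_t`, avoiding third-order derivatives;
- `V̂n3,B` (parametric bootstrap): n/(B−1) times the centred cross-product
  of Dn(θ̂*_b; Y*_b) over B refitted resamples from the fitted law.

ζ₁/ζ₂ are referred to χ²_q; ζ₃ to Hotelling's T²(q, B−1) via the exact
scaled-F representation `ζ₃(B−q)/(q(B−1)) ~ F(q, B−q)` (no table lookups).
ζ₁B/ζ₂B recompute the full statistic — including its covariance
estimator, evaluated at each resample's own MLE — on every bootstrap
resample; the decision rule compares the observed statistic with the
⌈(1−α)B⌉-th order statistic of the replicates, and the reported p-value
uses the plus-one convention (1 + #{ζ* ≥ ζ})/(B + 1).  Away from ties the
two rules are equivalent, which the tests check.  A bootstrap refit that
fails to converge (or yields an ill-conditioned covariance) is replaced by
a fresh resample, with a hard cap of 10·B replacement draws; this keeps B
fixed, as the reference distributions require.  The covariance bootstrap
of ζ₃ and the critical-value bootstrap of ζ₁B/ζ₂B use independent
streams.

## Alternative data-generating processes

- **Kumaraswamy KW(ω, φ)** — median parametrization: shape-1 = φ and
  shape-2 = log(½)/log(1−ω^φ), making the median exactly ω; sampled by
  CDF inversion.
- **Unit Weibull UW(ω, φ)** — the τ = 0.5 quantile parametrization,
  `F(y) = 0.5^{(log y / log ω)^φ}` on (0,1); sampled by inversion.
- **Simplex S(μ, σ)** — mean μ, dispersion σ with σ² in the density's
  dispersion slot: `f = [2πσ²(y(1−y))³]^{−1/2} exp(−(y−μ)²/(2σ² y(1−y)
  μ²(1−μ)²))`.  Both σ-vs-σ² conventions exist in the literature; this
  package's choice was fixed by simulation — it reproduces the published
  ζ₃ power under S(0.75, 2) at n = 100 (≈22%), while the alternative
  convention gives ≈15%.  No closed-form sampler exists, so sampling
  inverts a trapezoid-integrated CDF tabulated on a 4096-point
  logit-spaced grid (accuracy far below Monte Carlo noise; the analytic
  density is verified to integrate to one by quadrature).
- **Beta mean-regression** — `logit(μ_t) = β₁ + β₂ x_t` with constant
  precision and covariates drawn i.i.d. log-normal with log-scale sd 0.5
  (the literal `rlnorm(n, 0, 0.5)` reading), redrawn on every Monte Carlo
  replication so each sample is i.i.d. from the resulting mixture.  Power
  against this alternative is very sensitive to the realized covariate
  spread: over fixed covariate draws at n = 100 the conditional ζ₃ power
  ranges from ≈0.5 to ≈1.0, so a study that fixes one covariate vector
  per cell can land anywhere in that range, while this package reports
  the unconditional power (≈0.8 at nominal 10%).
- **Zero-inflated beta** — exact zeros with probability λ; before a beta
  fit, boundary values are mapped by `[y(n−1) + 0.5]/n` (0 → 0.5/n,
  1 → (n−0.5)/n), the standard practice for boundary observations.

## Monte Carlo harness

Per-replication random streams are spawned from `SeedSequence([seed, n])`,
so every cell is deterministic and independent of execution order or
parallel scheduling.  Rates are reported with binomial standard errors
`sqrt(r(1−r)/R)`; replications whose outer fit fails are counted and
excluded (in practice the failure rate is zero at the study's parameter
values).  For size-adjusted power of ζ₁/ζ₂ the null archive is simulated
at the pseudo-true beta parameters, obtained by fitting the beta model to
one sample of 10⁶ draws from the alternative — the Kullback–Leibler
projection.  The α-matched size–power curves are insensitive to this
choice by construction; the plain power tables inherit it.  Named
replication profiles: `paper` (R = 5000, B = 500) and `desk` (R = 1000,
B = 249), the scale used by the acceptance checks and script; at desk
scale each experiment runs in seconds to a couple of minutes on one CPU.

The acceptance tests assert published rejection rates within two combined
binomial standard errors (desk + published replication counts).  Because a
correctly calibrated rate still leaves its band a few percent of the time
in any single run, each stochastic check uses a fixed two-stage design:
one desk-scale run, and on a miss, one confirmation run at 4× replication
with an independently derived seed, asserted at its own tighter band.  A
genuinely miscalibrated rate fails both stages — the beta mean-regression
power cell does exactly that, for the covariate-conditioning reason
described above.

## Applied workflow

`read_rates` ingests a CSV (optional per-hundred scaling and cluster
labels); boundary values are rejected unless the replacement rule is
explicitly enabled.  Cluster-robust covariance is the score-cluster
sandwich `A⁻¹(Σ_g s_g s_gᵀ)A⁻¹` with A the total observed Hessian at the
MLE; singleton clusters recover the heteroskedasticity-robust sandwich,
and a G/(G−1) small-cluster correction is available by flag (off by
default).  `analyze` runs the fit, the three bootstrap tests (default
B = 1000; the harness's simulation default is 500), the asymptotic tests
only when n ≥ 500 (they are unreliable below that), alternative-family
fits by BFGS from a small grid of dispersion starts, and the
AIC/AICc/BIC/HQIC table.  All families compared have k = 2 parameters, so
criterion orderings reduce to log-likelihood orderings.

## Synthetic fixtures and what they show

`synthetic_period1_rates` draws n = 50 beta observations at (μ, φ) =
(0.09, 40) — a homogeneous low-rate regime; `synthetic_two_regime_rates`
mixes halves at (0.09, 40) and (0.21, 28) — pooled data from two regimes
with different means and precisions.  These emulate the *moments* of real
state-level rate data and nothing else: no spatial correlation, no
cumulative construction, no covariates.  Passing tests on them show the
machinery is calibrated under the null and sensitive to mixture-type
heterogeneity in aggregate; they say nothing about any particular real
dataset.  The two-regime mixture is a weak alternative: ζ₃ has
essentially no power against it at n ≤ 250, while ζ₁B/ζ₂B reject at
roughly 3–4× the nominal 5% rate at n = 100 — single draws are often not
rejected, and the fixture test therefore asserts an elevated rejection
*frequency* across seeds, not rejection of one sample.

## Known limitations

- The q = 3 variant is exposed but near-singular covariances make it
  fragile at low dispersion; that fragility is the reason q = 2 is the
  default.
- ζ₃'s power can be far below the χ²-bootstrap variants under some
  alternatives (simplex; mild mixtures), matching its published behaviour;
  it is not a uniformly best test.
- The simplex sampler is an interpolated numeric inversion; absolute CDF
  accuracy is ~1e−6, ample for Monte Carlo work but not for extreme-tail
  studies.
- Power numbers under the beta mean-regression process are unconditional
  over covariate draws; conditioning on a fixed design changes them
  substantially (see above).
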