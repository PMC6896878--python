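# Methods

`crtspill` reanalyzes a cluster randomized trial (CRT) of insecticide-treated
bed nets from a spatial point of view: does the intervention's benefit leak
across cluster boundaries to nearby control households (a spatial indirect
or "spillover" effect), and do spatially structured models change the trial's
conclusion?  Because no such trial's microdata are bundled here, every
analysis runs against a synthetic trial generator whose defaults emulate the
scale and structure of a large historical bed-net CRT: 96 contiguous
clusters, ~124 household compounds per cluster, all-cause child deaths with
household-level expected deaths as a Poisson offset.

## Outcome model

All models are Poisson log-linear in the standardized mortality ratio (SMR):

    O_h ~ Poisson(E_h * exp(eta_h))

with `O_h` observed and `E_h` expected deaths for household `h`.  Because
`log E_h` enters as an offset, every coefficient acts multiplicatively on
the SMR scale.  The linear predictor is

    eta_h = alpha + beta * x_j [+ psi * d_h / 100] [+ ...] + random effects

with `x_j` the cluster's arm (1 = bed nets) and `d_h` the household's
distance to the nearest opposite-arm household ("discordant distance").
`exp(beta)` is the intervention SMR ratio and `exp(psi)` the mortality
multiplier per additional 100 m from the nearest discordant household.
The distance covariate can enter linearly, with a quadratic term, capped
(`min(d, R)/100`), or as a binary threshold indicator (default 400 m) with
an intervention interaction.

### Random-effect structures

- **iid** — independent Normal(0, σ_u²) intercept per cluster; the standard
  multilevel CRT analysis.
- **car** — intrinsic conditional autoregressive (Besag) effect on the
  Queen's-case cluster contiguity graph, precision τ(D − W), sum-to-zero
  constrained; requires aggregating households to one observation per
  cluster and therefore only cluster-constant covariates.
- **bym** — Besag–York–Mollié convolution (IID + ICAR) at household level.
- **gp** — household-level zero-mean Gaussian field with exponential
  covariance σ² exp(−d/ρ) (the Matérn ν = 1/2 member), evaluated with an
  exact dense covariance.  Above a configurable cap (default 3,000
  households) the fit runs on a seeded household subsample; dense n³
  algebra is the deliberate alternative to sparse-approximation machinery
  at these problem sizes.

### Inference

The engine (`laplace_map`) is a nested Laplace approximation: for given
variance parameters θ, a joint Newton ascent finds the mode of the
penalized Poisson log-likelihood over fixed and random effects; θ then
maximizes the Laplace-approximate marginal likelihood (random effects
integrated out via the mode and curvature, fixed effects profiled).
Weakly-informative penalties — Normal(0, 10²) on fixed effects and
half-Normal(0, 1) on standard deviations — stabilize near-degenerate fits
without materially moving well-identified estimates.  95% intervals are
Wald intervals from the joint precision at the mode; the reported
`sigma_icar` is the ICAR conditional scale 1/√τ, not a marginal SD.

Numerical choices: the ICAR precision gets a 1e-6 propriety jitter and the
sum-to-zero constraint is imposed exactly by an orthonormal null-space
reparametrization; the GP covariance gets a 1e-8 diagonal jitter; the GP
range ρ is a fixed hyperparameter (default 1,000 m) rather than optimized,
since profiling it costs a dense Cholesky per evaluation and the intervention
and spillover contrasts are insensitive to it at these scales; linear
predictors are clipped at ±30 before exponentiation; Newton uses step
halving and the one-dimensional θ searches are bounded in log σ ∈
[log 1e-3, log 5].  Households with `expected = 0` (and `observed = 0`) are
excluded from likelihoods with a logged count; `expected = 0` with deaths
is a validation error.  Fits are refused when an arm has fewer than 30
households (`min_arm_size`).

In tests the IID fit is cross-checked against an independent
Gauss–Hermite-quadrature maximum-likelihood implementation (exact
integration of the cluster effects) and, in the σ_u → 0 limit, against a
plain Poisson GLM.

The global interaction test is a likelihood-ratio test on the Laplace
marginal likelihood (χ², 1 df).  The parametric bootstrap re-draws cluster
effects from N(0, σ̂_u²) and counts from the fitted Poisson means, refits,
and reports the percentile interval of the collected coefficient; >5%
refit failures or a zero-width interval flag the result.

## Exploratory spatial statistics

The spatial weight matrix is binary Queen's-case contiguity (shared
boundary point or vertex, within snap tolerance), deliberately not
row-standardized; Moran's I uses the matching (n/S0) normalization:

    I = (n / S0) * Σ_ij w_ij z_i z_j / Σ_i z_i²

Join counts tally adjacent cluster pairs by arm combination.  Inference for
both is Monte Carlo: labels or values are permuted over clusters and
p = (1 + #{null ≥ observed}) / (1 + n_sim), one-sided "greater" by default
(n_sim = 999).  Residual autocorrelation uses cluster-mean household
Pearson residuals from the IID fit (means, not sums, so cluster size does
not masquerade as signal); arm-stratified Moran's I uses the induced
subgraph of the kept clusters.

GWR fits, at each cluster centroid, a kernel-weighted Poisson regression of
deaths on the intervention with the log-expected offset and no cluster
random effect, over households within a fixed radius (bisquare kernel by
default, uniform available).  The bandwidth is user-set or chosen as the
smallest grid radius giving every focal cluster a minimum household count
in each arm; focal points below that minimum are flagged undefined rather
than extrapolated.

## Cluster reallocation

The diagnostic dilates (buffers) the union of one arm's polygons outward in
steps (default 0–1,000 m by 100 m), reassigns every opposite-arm household
inside the buffered union to the dilated arm, refits the trial model, and
traces the intervention estimate against the buffer.  Buffering the union
is equivalent to reassigning households whose point-to-union distance is at
most the buffer, which makes the reassigned sets nested across buffers.
Reassigned households join pseudo-clusters keyed by their nearest original
dilated-arm cluster so the multilevel structure stays intact; steps that
shrink an arm below `min_arm_size` are recorded as degenerate, with no
estimate.  The curve is descriptive; no test statistic is attached.

Expected behavior, verified by simulation in the test suite: with no
spillover, reassignment mixes the arms and the estimate drifts toward
SMR 1 as the buffer grows, in both directions.  A spillover from the
intervention reduces that attenuation when the intervention arm is dilated
(the partially protected near-boundary controls leave the control arm), and
with a strong near-field spillover — e.g. a near/far mortality contrast of
0.74 within 400 m — the estimate strengthens outright over the spillover's
range.  At the generator's default spillover (1.7% per 100 m, i.e. a
maximal near-field dip of 6.5%) the strengthening is too small to overcome
dilution, so the curve only attenuates more slowly; the acceptance test
asserting outright strengthening at those defaults fails, and is retained
as a factual record of that limit.

## Synthetic trial generator

Geography: cluster polygons are the Voronoi tessellation of uniformly
placed seeds clipped to the study rectangle (30 × 20 km by default, ~6.25
km² per cluster), so clusters are contiguous and space-filling as in the
emulated trial; household counts are Poisson around the per-cluster mean
and locations uniform within the polygon; arms are a permuted balanced 1:1
vector over clusters.  `SimulationConfig.scaled(k, m)` shrinks the
rectangle to keep per-cluster area (and hence distance scales) fixed while
reducing cluster count — the scaled study conditions used by the faster
simulation tests (12 clusters, ~600 households) were chosen so distances in
meters remain comparable to the full design.

Outcomes: household expected deaths are Gamma(shape 2.0, mean 0.06) —
compounds vary in child-time at risk; the linear predictor adds the
intervention effect (default log 0.83), an IID cluster effect (SD 0.2), an
optional ICAR or GP field, and an asymmetric spillover: control households
get `psi * min(d, R)/100` with d the distance to the nearest bed-net
household (default psi = log 1.017, R = 400 m), intervention households sit
at the plateau `psi * R/100`.  Beyond the range the arms therefore differ
exactly by beta, and control mortality falls as bed nets get closer while
intervention mortality is flat in distance — the asymmetry the stratified
distance analysis is designed to detect.  With `R = inf` the generator
switches to symmetric pure linear decay `psi * d/100` in both arms (the
asymmetric form has no finite infinite-range limit); this is the
correctly-specified setting for linear-distance recovery tests.  The
intercept is set so the control arm's marginal SMR at the plateau equals a
configurable baseline (default 1.37), with −variance/2 corrections for the
lognormal random effects.  `GroundTruth` stores every realized parameter
and linear predictor, so tests can reconstruct each household's Poisson
mean exactly.

What the generator does not emulate: real household clustering within
compound groups, demographic structure behind the expected deaths,
non-Euclidean movement, inter-cluster gaps, and mosquito dynamics.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not the epidemiological fidelity of that model.

## Problem sizes and defaults used in checked runs

The test suite runs the recovery, calibration and reallocation simulations
at the scaled design (12 clusters, ~600 or ~1,500 households; 20–100
replicates), with the Gaussian process capped at 1,000 households — sizes
at which the checked properties are already informative.  The acceptance
script (`scripts/acceptance.py`) runs the full pipeline once at the
emulated study scale (96 clusters, ~12,000 households), with the GP
subsample capped at 1,200 households and 200 bootstrap draws.  Permutation
tests use 999 draws in headline runs and 199 in replicated simulations.

## Known limitations

- Wald/Laplace intervals, not full posteriors; with few clusters they can
  be slightly liberal (empirical coverage is tested at 0.85–1.00 over
  simulation replicates).
- The GP range is fixed, not estimated, and GP fits above the cap see only
  a household subsample.
- The linear distance-per-100 m spillover coefficient is attenuated
  whenever the true decay is range-limited and the model is fitted over all
  distances (both arms included); the capped and threshold forms exist for
  exactly that reason.
- CAR fits require cluster-constant covariates (a consequence of
  aggregation), so there is no CAR+distance variant.
- Permutation p-values are conditional Monte Carlo p-values with the +1
  correction; they are never exactly zero.
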