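# Methods

## The model

Ovarian cycling is modelled at the treatment level.  A female's
pre-ovulatory period is the sum of a follicular phase, taken constant
within a treatment (τ, days), and a highly variable component modelled
as the waiting time of a homogeneous Poisson process with per-day rate
λ.  Pre-ovulatory durations therefore follow a shifted exponential law
with density λe^{−λ(x−τ)} on x ≥ τ, mean τ + 1/λ and SD 1/λ.  τ is a
nuisance parameter — it never enters a synchrony statement — but a good
estimate of λ requires estimating it jointly.

Durations are pooled across animals within each treatment; no
per-animal random effects are modelled.  Completed periods only are
used — censored periods at the observation-window edge are dropped
without a censoring likelihood (see *Limitations*).

Calving time is B = M + G, time to mating plus an independent normal
gestation.  Under the assumption that adult females are not
mate-limited and mate within a short periovulatory interval, M is the
time to ovulation, so B follows a shifted ex-Gaussian whose variance
1/λ² + σ² does not involve the location parameters μ and τ.  Synchrony
comparisons between groups therefore depend only on (λ, σ).

## Estimators

With m = min of the pooled durations and S = Σ(x − m), the
minimum-variance-unbiased pair for the two-parameter exponential family
is

- scale:  1/λ̂ = S/(n−1)   (unbiased for the mean waiting time 1/λ),
- shift:  τ̂ = m − S/(n(n−1))   (unbiased for τ).

The reported rate is the reciprocal of the unbiased scale estimate,
λ̂ = (n−1)/S; it carries the standard (n−1)/(n−2) reciprocal-moment
factor relative to an unbiased estimate of λ itself, and relates to the
maximum-likelihood rate n/S by the factor (n−1)/n.  The unbiasedness of
(1/λ̂, τ̂) is verified by simulation in the test suite.  Negative shift
estimates (possible when the smallest duration is an outlier toward 0)
are clamped to 0 with a warning, because a negative follicular phase is
meaningless.  Fitting requires n ≥ 3 and non-identical durations.

Uncertainty on (λ̂, τ̂) is quantified by parametric bootstrap:
simulate datasets of the original size from the fitted law, refit each,
take central percentile intervals.  The bootstrap keeps estimator
uncertainty in the same family as the prediction machinery.

## The T80 statistic

T80 is the width of the 80% highest density region — the shortest
interval containing 80% of the event-time mass; 80% is the conventional
coverage in the synchrony literature and is configurable everywhere.
T80 is always computed from a distribution (fitted or composed), never
by kernel estimation on raw event times; `empirical_quantile` is an
explicitly labelled sample-based adapter for exploration only.

- Shifted exponential: the density is monotone decreasing on its
  support, so the HDR is anchored at τ with closed-form width
  ln(1/(1−p))/λ.
- General unimodal laws: `hdr_numeric` minimises
  quantile(u+p) − quantile(u) over u ∈ [0, 1−p] on a 10⁴-point grid
  with bounded scalar refinement (tolerance 1e−4 on u).  For unimodal
  densities the objective is unimodal in u, the derivative
  1/f(Q(u+p)) − 1/f(Q(u)) changing sign once.  Ties — flat densities,
  where every position has equal width — resolve toward the smallest u,
  with a relative tolerance of 1e−9 so floating noise cannot move the
  interval off the left edge.  Multimodal HDRs (unions of intervals)
  are out of scope.
- Ex-Gaussian: the quantile function is the numerically inverted CDF
  (bracketed root-finding, absolute tolerance 1e−8 d).  The CDF and
  density use scaled-complementary-error-function (erfcx) and
  log-normal-CDF forms so that nothing overflows even when λσ² is
  large; the density formula reduces to
  (λ/2)·erfcx(z)·exp(−(b−μ−τ)²/2σ²) on the z ≥ 0 branch, which is the
  algebraically exact cancellation of the exploding exponential.

For bootstrap ensembles a fast path exploits the exact scale reduction
T80(λ, σ) = σ·W(λσ): W is tabulated once per coverage on a 241-point
log grid over λσ ∈ [10⁻³, 10³] and monotone-cubic (PCHIP)
interpolated, with the exact exponential and normal asymptotes outside
the table.  Agreement with the direct numeric search is ~10⁻⁴ d and is
asserted in the tests.

## Permutation test

The null hypothesis is equal synchrony; the alternative, that controls
take longer to reach 80% ovulation, is one-sided on
D = T80(Control) − T80(Playback).  Labels are permuted at the animal
level, preserving group sizes: periods within an animal share that
animal's cycling rate and are not exchangeable between groups, whereas
whole animals are under the null.  Within each of the 50,000
permutations the statistic is recomputed exactly as for the observed
data (pool, MVU fit, closed-form T80).  The p-value is the raw
proportion of permuted D at or above the observed D; a (k+1)/(n+1)
variant is available.  Period-level permutation is offered behind
`unit="period"` for sensitivity analysis.  With five animals per group
there are C(10,5) = 252 distinct assignments, so the exact conditional
null p-value is uniform on {1/252, …, 1} and the achievable type-I
rate at α = 0.05 is 12/252 ≈ 0.048; the test suite verifies null
uniformity and this rate empirically.

## Bootstrap predictions

Each mating replicate simulates n durations from the fitted law, refits
by MVU, and records the refit's closed-form T80.  Because the refit
rate is (n−1)/S with S ~ Gamma(n−1, 1/λ), the predicted-T80 median sits
a factor median[Γ(n−1)]/(n−1) (≈ 0.990 at n=34, ≈ 0.979 at n=17) below
the input T80 — the small downward displacement visible in the median
predictions.

Calving replicates reuse the same rate-drawing scheme and add a
gestation SD drawn from the allometry's prediction distribution: in
log2 space, center = intercept + slope·log2(258), scale =
s·√(1 + 1/n + (x₀−x̄)²/Sxx) with n−2 degrees of freedom (the standard
OLS prediction distribution for a new species), back-transformed
through 2^x so draws are strictly positive.  Draws below 0.5 d are
redrawn for numeric stability of the ex-Gaussian inversion (a
degenerate, zero-spread prediction bypasses the floor so σ→0 limits
remain reachable).  `SigmaPrediction.from_point` builds the
distribution directly from a reported central estimate, with default
predictive scale 0.306 log2 units and 35 degrees of freedom — the
values implied by the default synthetic allometry below.

## Synthetic data

`simulate_experiment` emulates the study design: per treatment, 5
animals observed 182 days, alternating pre-ovulatory draws from the
treatment's shifted exponential (defaults: Playback λ = ln5/15.70 ≈
0.103/d, τ = 5.71 d; Control λ = ln5/53.72 ≈ 0.030/d, τ = 4.03 d —
rates back-derived from the reported group T80 estimates) and constant
12-day post-ovulatory periods.  The luteal length is not modelled in
the source analysis and never enters pre-ovulatory inference; 12 d is a
realistic bovid value that sets how many cycles fit in the window.
Periods tile the window exactly; the final partial period is censored.
A `rounding` flag quantises transition times up to the 3-day sampling
grid (default off so analytic oracles are exact; real collection was at
≤3-day resolution, daily versus 3-day binning being unreported).

The 3-day start filter removes an animal's first pre-ovulatory record
when it ends at or before day 3 (inclusive reading of "within three
days", configurable): such females were likely already in follicular
phase at the start and carry no treatment signal.

`simulate_gestation_table` generates a 41-species allometry: log2 means
uniform over 20–700 d, SDs from a slope-0.9 power law with log2-normal
residuals (SD 0.3), intercept derived so the noiseless prediction at a
258-day mean is exactly 5.74 d, plus 3 primate and 1 elephant rows on
an offset relationship to exercise the exclusion filter (37 retained
species).  The slope and noise are choices of a realistic mammalian
allometry calibrated to the reported prediction point; they are a
stand-in for the published cross-species dataset, not a claim about it.

What the generators do *not* emulate: endocrine classification noise in
period boundaries, between-animal heterogeneity in λ or τ within a
treatment, non-constant luteal phases, and seasonality within the
window.  Passing tests therefore show the statistical machinery is
correct under the model's own assumptions, not that those assumptions
hold in real herds.

A property of the design worth knowing: completed periods extracted
from a fixed window are length-biased, because long periods are
preferentially censored at the edge.  At the 26-week window this
inflates the fitted rate by roughly 6% (Playback) and 22% (Control)
regardless of how many animals are simulated — an inspection effect
inherent to windowed renewal observation, affecting the real study
design equally.  Parameter-recovery oracles in the tests therefore use
windows long enough to make the bias negligible, while a separate test
checks that study-scale fits stay within their bootstrap CIs of truth.

## Problem sizes and determinism

Bootstrap predictions use the full 15,000 replicates and the
permutation default is 50,000; the reproduction suite runs these at
full size (the fast scaled T80 path makes the calving bootstrap
seconds).  Simulation-calibration tests use 10⁴–10⁶ draws sized so
Monte-Carlo error sits well below each asserted tolerance, and the
null-uniformity check runs 500 replicate experiments at 2,000
permutations — enough that the anti-conservatism of the raw-proportion
p-value estimator at tiny permutation counts is negligible.  Every
stochastic routine takes an explicit seed or Generator; the pipeline
spawns per-stage child seeds from one master seed and records them in
its report, so identical configurations produce identical reports.

## Limitations

- Pooling ignores animal-level rate heterogeneity; with it, pooled
  durations would be over-dispersed relative to the shifted exponential.
- Censored periods are discarded rather than likelihood-weighted, so
  window-edge length bias (above) is part of the estimand at short
  windows.
- The gestation-SD allometry is synthetic-calibrated; its residual
  spread (hence the calving prediction distribution's width, though not
  materially its median) is an assumption.
- The bootstrap CI method for (λ̂, τ̂) is a package choice; the source
  analysis reports 95% CIs without naming a method.
- Multimodal time-to-event laws are outside the HDR implementation's
  contract.
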