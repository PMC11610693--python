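# Methods

This note records the scientific and numerical choices behind `seedbed`:
what each stage computes, the assumptions it makes, and what the synthetic
data can and cannot establish.

## Wet-thermal germination model

Germination progress of the 35 % subpopulation accrues only during hours
that are simultaneously warm (soil temperature T > 0 °C) and wet (soil
water potential ψ > −1.25 MPa) at 2 cm depth; both inequalities are strict,
so an hour at exactly 0 °C or exactly −1.25 MPa contributes nothing. Within
those conditions the hourly rate is a temperature polynomial with
coefficients (c₀, c₁, c₂) = (1.29×10⁻⁴, 6.16×10⁻⁴, −1.25×10⁻⁵).

Two readings of this coefficient triple are defensible, because the source
prints both first-order terms against T without an explicit square. The
package defaults to the quadratic rate(T) = c₀ + c₁T + c₂T², the only
arrangement that gives a biologically plausible wet-thermal curve — a
concave-down response with optimum near 25 °C and germination of the 35 %
subpopulation in roughly five to six days of continuously wet 20 °C soil
(rate(20) ≈ 0.00745 h⁻¹ → ≈ 134 h to progress 1). The literal linear
reading c₀ + T(c₁ + c₂) is selectable via `RateCurveParams(form="linear")`;
the two agree in the T → 0⁺ limit (c₀). Above ≈ 49 °C the quadratic turns
negative and is clipped to zero: rates cannot be negative and the curve is
only meaningful over the suboptimal-to-optimal range.

Rate sums accumulate over *all* qualifying hours of a window with no
sequential-wetting reset: the metric deliberately credits many short wet
windows as much as one long one. Monthly sums are computed for complete
calendar months only (partial boundary months are dropped with a warning);
the fall sum (October + November + December) attaches to the *following*
calendar year, the conditions immediately preceding a growing-season
observation; the spring sum is March of the observation year itself.
Windows passed to `rate_sum` are half-open `[start, end)`; a window wholly
disjoint from the series is an empty sum (0), while a window that only
partially overlaps raises — silently truncating a seasonal sum would bias
it low. Complete hourly series are required; gaps are an error naming the
first offending timestamp.

## Covariates

Site means are climatology: they are taken over the full simulated
reference period (default 1990–2019), not only over observed years, because
the hindcast needs covariates in years without observations and "an average
site" should not depend on when it happened to be visited. Spatial z-scores
use the sample (n−1) SD across sites; temporal anomalies use the sample SD
across years within each site. Scaling constants are computed on the
training watersheds only and frozen (`ScalingConstants`, serializable to
YAML) for test data and hindcasts — the leakage-safe choice when data are
split spatially after scaling. A site whose seasonal rate sum never varies
(e.g. a site too cold to accumulate progress in any year), or with a single
year of data, gets temporal anomalies of exactly 0: "an average year for
this site". All four covariates are invariant to multiplying every rate sum
by a positive constant.

`screen_covariates` reproduces the covariate-selection step as a ranking of
candidate monthly/seasonal metrics by |Pearson r| with percent cover (ties
alphabetical, undefined correlations last); the four model covariates are
otherwise fixed.

## Additive models

Both models share the structure g(E[y]) = β₀ + Σⱼ sⱼ(xⱼ) with one
penalized cubic B-spline smooth per covariate (basis dimension k = 10,
knots at quantiles of the training values so they spread evenly through the
data; equal spacing is configurable). The presence model is binomial-logit
on the cover > 2 % indicator; the cover model is Gaussian-identity on raw
percent cover including zeros (a transformation hook is deliberately not
provided — families beyond these two are out of scope).

Smoothing parameters are selected per term by a deterministic
coordinate-descent search over a log₁₀ grid (default 10⁻³…10⁵, nine points,
two sweeps), minimizing a BIC computed on effective degrees of freedom.
BIC was chosen as the default because, like REML, it is conservative:
on pure-noise terms it shrinks smooths to the (near-linear) null space of
the second-derivative penalty, where AIC- and GCV-style criteria are known
to undersmooth and chase noise. AIC and GCV remain available via
`GamConfig(criterion=...)`. Fits are penalized IRLS via
`statsmodels.GLMGam`; identical data and config give identical coefficients.

Partial-effect curves are reported on the linear-predictor scale, centered
by subtracting each smooth's mean contribution over the training rows (the
usual identifiability convention), with pointwise standard errors from the
coefficient covariance. Predictions clip covariates to the training range —
constant extrapolation of each smooth — and flag such rows; classification
uses a strict probability threshold (default 0.5, configurable), so a
probability exactly at the threshold is a predicted absence.
`model_diagnostics` reports per-term EDF against basis dimension (flagging
EDF > 0.9(k−1), a sign the basis may be constraining the fit), a
Pearson-statistic dispersion estimate, and randomized-quantile residual
summaries (seeded jitter for the binomial family).

Models serialize to a versioned JSON container that includes the training
covariate matrix: spline knots are a deterministic function of those
values, so the basis is reconstructed exactly at load time.

## Blocked validation and metrics

Watershed units are the sampling unit of the train/test split:
`round(test_fraction × n_watersheds)` units (default a third) are drawn
uniformly into the test block, so no site appears on both sides and the
realized observation fraction varies. Metrics are sensitivity (presence
accuracy), specificity (absence accuracy), their unweighted mean (balanced
accuracy), overall accuracy, and — for cover — the squared Pearson
correlation of observed vs predicted, chosen for comparability with
remote-sensing cover models (the 1 − SSE/SST variant is available; note
squared correlation is sign-blind, which is logged when it matters).

## Hindcast

Sites are stratified into elevation terciles (group sizes differ by at most
one; ties broken by site id) and aspect quarters (N = [315°, 45°),
E = [45°, 135°), S = [135°, 225°), W = [225°, 315°)). For every year of the
window the occupied fraction per stratum counts sites with predicted
probability strictly above the threshold. Trends are OLS slopes of fraction
on year; the relative change over the window is computed from the fitted
line's endpoints (robust to single-year noise) and is undefined when the
fitted start is ≤ 0. Temporal anomalies for hindcast years use site
mean/SD over the full window, consistent with the covariate module's
reference-period convention.

## Synthetic data

The microclimate emulator is statistical, not physical — it reproduces only
the features the rate-sum chain consumes. Soil temperature is an annual
mean declining with elevation at 6.5 °C km⁻¹ (9 °C at the 1500 m reference),
an annual cosine (amplitude 10 °C, peak day 205), a diurnal cosine
(amplitude 5 °C, peak 14:00 — damped relative to air temperature, as at
2 cm depth), a south-facing warm bias (2 °C × sin(slope)), and AR(1) noise
(φ = 0.95, marginal SD 1.5 °C). Water potential jumps to −0.03 MPa at
Poisson wetting events (mean interval 5 days in the October–May wet season,
30 days otherwise) and decays exponentially toward −8 MPa with a 240 h time
constant in cool months and 72 h in June–September. These defaults were
chosen once to mimic seasonal wet/dry structure and elevation gradients of
sagebrush-steppe seedbeds: they yield a far higher fraction of wet hours in
October–May than June–September, spring and fall rate sums that decline
strongly with elevation, and soil dry most of the summer. An optional
linear warming trend can be applied to configurable months and confined
below an elevation band (full effect below 1200 m, tapering to none above
1800 m by default) to emulate climate-change scenarios. Deliberately
absent: snowpack, canopy shading, soil-texture effects on retention
(texture fields are generated only for schema compatibility with real
soil-model output), and timezone/DST conventions (timestamps are local and
continuous; leap days are included).

Observations are drawn from four known effect functions matching the
qualitative shapes the models should recover: concave-down in
`fall_spatial` (peak at +0.5 SD), saturating-increasing in
`spring_spatial`, increasing concave-down in `fall_temporal`, linear
decreasing in `spring_temporal`, with intercept β₀ = −1.5 (≈ 50 %
prevalence). Cover at presence sites is Gaussian (intercept 12 %, gain 3
per logit of favorability, SD 5) truncated to (2, 100] so a generated
presence always exceeds the 2 % presence threshold; absences have cover 0.
At most one observation per site-year is emitted, matching a survey design
with no repeat visits.

Passing tests on these data show that the chain recovers known structure
under its own generative assumptions — smooth additive effects, correct
covariates, spatially exchangeable watersheds. They do not show robustness
to what real data add: observation error in cover, residual spatial
autocorrelation within watersheds, non-additive interactions, or soil
physics the emulator lacks.

## Problem sizes and reproducibility

The test suite exercises the chain at 200 sites × 15 observation years
(~2000 observations, 20 replicates) for effect recovery and holdout skill,
90 sites × 30 years for the warming hindcast analog, and 40 sites for
bit-identical pipeline reruns; these sizes give stable statistics for the
properties checked while keeping the suite quick on a single CPU. All
randomness derives from explicit integer seeds; the pipeline spawns
per-stage and per-site seeds from the single top-level seed via
`numpy.random.SeedSequence`, so any run is reproducible from its config
alone.

## Known limitations

- Only the 35 % subpopulation curve is implemented; no per-seedlot fits,
  other percentiles, or continuous water-potential response
  (hydrothermal-time models).
- No interaction smooths, tensor products, spatial random effects, or
  families better matched to proportion data (beta, Tweedie); the Gaussian
  cover model can predict outside [0, 100] (a clamped convenience column is
  provided).
- Smoothness selection is grid-based per term; a full REML optimization is
  not available in the underlying fitting library.
- The hindcast extrapolates the fitted response to past microclimate; it
  inherits whatever bias the constant-extrapolation rule introduces for
  covariates outside the training range (such rows are flagged).
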