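# Methods

## The problem

District-level prevalence of global acute malnutrition (GAM) among children
6–59 months is surveyed twice a year (January and July) in Somalia-style
food-security monitoring, while most candidate drivers — conflict events,
rainfall anomaly, vegetation (NDVI), IPC phase-3+ population share, crop and
demographic variables — arrive monthly or biannually. The package answers
two questions on such a panel: *which covariates are associated with GAM,
and how (linearly or not)?* and *can the 6-month-ahead change in GAM be
forecast at the district level better than trivial benchmarks?*

## Synthetic panel generator

All testing runs on a seeded generator (`gamcast.synthetic`) emulating the
real panel's geometry: 74 districts in 18 regions, July 2017 – July 2021
(49 months, 9 biannual survey rounds), covariate means/SDs matching the
published district-level summary statistics (e.g. rainfall anomaly
µ = −1.2 mm, σ = 25.1 mm; IPC share µ = 0.14, σ = 0.11).

Each covariate is a latent monthly AR(1) process (coefficient 0.9) plus an
additive seasonal sinusoid with district-level phase jitter, rescaled to
unit variance and mapped to native units. GAM is

    GAM_d(t) = baseline_d + Σ_j link_j(z_{j,d}(t−6)) + season_d(t) + ε_d(t),

clipped to [0, 100] after noise (ε ~ N(0, 1 pp) by default), observed at
January/July months only. Three link families are provided — linear,
hard threshold (step) and hinge (piecewise-linear kink) — because the
field literature reports threshold-like covariate→GAM relationships without
committing to a functional form. The 6-month lag inside the links makes the
previous survey round's covariates genuinely predictive. Default links:
NDVI linear (−1.5 pp/SD), IPC hinge (+1.5 pp/SD above +0.25 SD), crop
diversity threshold (−1.2 pp), rainfall hinge (−1.2 pp/SD above −0.25 SD);
conflicts, crop production, population and density are null links so
false-selection behaviour is observable. Missingness removes 1–3 biannual
GAM values from a seeded random 9/74 of districts (district identity is
exchangeable; the real pattern is unknown).

What the generator does *not* emulate: spatial autocorrelation between
neighbouring districts, conflict burstiness, survey-design effects, and
covariate cross-correlations. Passing recovery tests therefore demonstrates
internal correctness of the estimators and decision rules under known
truth, not performance on real Somalia data.

## Preprocessing conventions

* z-scores use the sample SD (n−1); normalisation of the monthly
  (relationship) table is full-sample, while forecasting features are
  normalised with training-split statistics only, to avoid leakage (a
  `normalise_full_sample` flag restores pre-split normalisation).
* Biannual→monthly: linear interpolation in the calendar-month index, no
  extrapolation beyond the first/last observation.
* Monthly→biannual: mean of the 6 months ending at (and including) the
  survey month (Feb–Jul for July, Aug–Jan for January); a window with any
  missing month yields a missing value.
* "Preceding 3 months" windows cover t−1..t−3, excluding the current month.
* Correlation pruning (|r| > 0.9) acts across *base variables*; lag/window
  variants of one base are intentionally collinear and are instead kept
  apart by the multiple-regression model structure.
* Spatial gap-filling for district-sparse variables uses the mean of
  observed adjacent districts, falling back to the national mean when no
  neighbour is observed.

## The uniform confidence band and the linearity test

The kernel regression uses the quartic (biweight) kernel and the
normal-reference bandwidth h = 1.06·σ̂·n^(−1/5). The 95% uniform band over a
grid of 100 points between the 5th and 95th covariate percentiles has
half-width

    [ σ̂²(g)·‖K‖₂² / (n·h·f̂(g)) ]^{1/2} · ( √(2δ log n) + c_α/√(2δ log n) ),

with ‖K‖₂² = 5/7, f̂ the same-kernel/same-bandwidth density estimate,
σ̂²(g) the kernel-weighted local variance of the residuals against the
fitted curve, δ = log(1/h̃)/log n for h̃ rescaled to the trimmed support, and
c_α = −log(−½·log(1−α)) the Gumbel quantile.

Two numerical choices deserve note. First, the extreme-value limit behind
such bands admits a second-order, kernel-dependent centering constant; for
the quartic kernel it is negative and, at practical sample sizes (n =
200–500 per region), pulls entire-curve coverage visibly below the nominal
level (Monte Carlo: ≈0.88 at n = 200). We omit it — the two factors are
asymptotically equivalent, and the leading-order factor keeps finite-sample
coverage at or slightly above 95% (MC: 0.96–0.97), which is the band's
contract. Second, this calibration is what gives the *strict* linearity
rule workable operating characteristics: a relationship is declared linear
only if the whole simultaneous Working–Hotelling band of the OLS line fits
inside the kernel band at every grid point — a deliberately conservative
finite-sample rule (the parametric band consumes part of the nonparametric
band's slack). With the calibrated band, a truly linear link passes
per-region about 70% of the time at n = 200, and the ≥50%-of-regions
aggregation then recovers linearity in essentially all replicates, while
hinge/threshold links of the default effect sizes are flagged nonlinear in
≈100% of replicates. A pointwise OLS-band mode is available behind a flag
for sensitivity analysis. Regions with fewer than 30 usable observations,
degenerate covariates or uncoverable grids are excluded from the regional
denominator and logged.

## Multiple regression

Each of the three models regresses GAM on month dummies (11, January
reference), region dummies (17, first region reference), the 6-month lag of
GAM, and one variant per covariate (model 1: original; model 2: 1- or
6-month lags; model 3: 6-month lags or 3-month windows). Standard errors
use the *panel* form of the Newey–West estimator (Bartlett kernel applied
within each district's time series, never across districts), with plug-in
truncation lag ⌊4(n/100)^{2/9}⌋; maxlags = 0 reduces to White's estimator.
Group significance of the month and region dummies comes from F-tests under
the same covariance.

## Forecasting design

β ∈ {5, 6} with the test set fixed at the last two survey rounds; with
β = 5 the intervening round is left unused rather than leaked into
training. Grid search minimises validation MAE (ties broken toward the
smaller model: fewer trees, shallower, larger split threshold, smaller
learning rate); the final refit uses the training periods only by default.
Default grids: random forest — trees {100, 300, 500}, max features
{√p, p/3, p}, min samples to split {2, 5, 10}; gradient boosting — the same
plus depth {2, 3, 5} and learning rate {0.01, 0.05, 0.1}. SES is tuned on
the validation round over α ∈ {0.1, …, 1.0} with F₁ = Y₁; α = 1 reproduces
the naive forecast exactly. One model is pooled across districts — nine
periods per district cannot support per-district models. All tree fits are
seeded and single-threaded, so identical configurations reproduce
byte-identical outputs.

Exact-zero changes are excluded from the quadrant denominator and counted
(the naive benchmark therefore has no direction accuracy — its predicted
change is identically zero).

## Problem sizes used in the checks

The test-suite and acceptance-script simulations use: 500 Monte-Carlo
replicates at n = 500 for band coverage; 50 replicates of 18 regions × 200
observations for nature recovery; 50 full-pipeline replicates for selection
recovery and 30 for the all-null false-selection rate; 10 seeded
strong-signal panels (active effect sizes doubled, noise SD 0.5 pp —
a regime where environmental drivers dominate survey noise) for the
forest-vs-naive benchmark comparison.

## Known limitations

* **Simple-regression inference on interpolated series is anti-conservative.**
  The monthly relationship table interpolates biannual GAM linearly, so up
  to six consecutive rows share two noisy survey endpoints; classical iid
  t-tests in the simple-regression step then overstate significance
  substantially. Under an all-null synthetic panel the per-variable
  false-selection rate is ≈0.70, far above the ≈0.26 familywise rate the
  0.05 boundary would imply for independent data — and the corresponding
  acceptance test is deliberately left failing at the nominal-implied
  bound rather than weakened to the dependence-inflated one. The published
  analysis design this package implements shows the same signature
  (near-universal "very high" simple associations); the multiple-regression
  step with panel-HAC errors is considerably better calibrated (≈0.16 per
  variant) but feeds the same either/or selection rule. Treat the selected
  set as inclusive screening, not as calibrated hypothesis tests.
* The uniform band is asymptotic; no bootstrap or bias correction is
  provided.
* The nature classification assumes independent observations within a
  region; interpolation-induced dependence makes full-pipeline verdicts
  lean nonlinear.
* Forecast skill estimates rest on 2 test rounds × ~65 districts with
  spatially dependent shocks in real data; synthetic results quantify
  method correctness, not expected field accuracy.
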