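# Methods

## Rates

The unit of analysis is the annualized monthly crude death rate per 100,000,
`CDR = D* / (P/12) × 100,000`.  Monthly exposure is exactly one-twelfth of
annual person-years — no within-year interpolation — and the month-length
adjustment `D* = D × (days_in_year/12) / days_in_month` is leap-aware, so a
constant daily death rate yields identical CDRs in every month of a year.
Two consequences worth knowing: (i) summing `D*` over a year reproduces the
raw annual death count only when daily rates are equal across months, and
(ii) a leap target year genuinely carries one extra day of deaths, worth
about +10 per 100,000 on a CDR of 3,650 — this is real mortality, not an
artifact, and the baselines fitted on mostly non-leap reference years do not
remove it.

Weekly (ISO-8601) death series are disaggregated to months by spreading each
week's deaths uniformly over its seven days and summing days by calendar
month.  Totals are conserved exactly over fully covered spans; monthly
counts become fractional and are deliberately not rounded, since everything
downstream is a continuous rate.  A requested month with any uncovered day
raises a coverage error rather than silently scaling.  Whether uniform
within-week allocation matches any particular statistical office's own
transformation is unknowable from published totals; it is the assumption
that adds no structure beyond the data.

## Baseline (expected-mortality) models

All three baselines fit one geographic unit at a time on a complete
(years × 12 months) reference panel, default 2015–2019, configurable down to
shorter windows (two years minimum for the trend model, three for
Lee-Carter).

**Method A** is the month-fixed-effects model: `α̂_m` is the mean of month
`m` over the reference years, and the prediction ignores the target year.

**Method B** adds a common linear trend in calendar year.  Because the panel
is balanced, the month dummies are orthogonal to the centered year
covariate, so the OLS solution is closed-form: the pooled slope
`β̂ = Σ_{t,m} (t−t̄)(CDR − mean_t CDR(·,m)) / (12 Σ(t−t̄)²)` and
`α̂_m = mean_t CDR(·,m) − β̂ t̄`.  This is numerically identical to a
normal-equations solve on the dummy-encoded design (the test suite checks
this against statsmodels and a brute-force solve) and makes the bootstrap
refit a single matrix operation.  Predictions are invariant to affine
recoding of the year covariate; the stored parametrization uses the
uncentered calendar year.  No exposure weighting is applied.  Fits are exact
to machine precision on noiseless linear data.

**Lee-Carter** adapts the classical log-bilinear mortality model with
calendar months in the role of age strata: `log CDR(t,m) = a_m + b_m k_t`.
`a_m` is the time-mean of log rates; `(b, k)` is the leading SVD component
of the centered log-rate matrix under the identification `Σb_m = 1`,
`Σk_t = 0` (re-centering `k` and absorbing the shift into `a`); the sign is
fixed by the `Σb = 1` normalization.  `k` is extrapolated as a random walk
with drift `(k_last − k_first)/(N−1)` rather than refitted.  A panel with no
time variation degenerates to `k ≡ 0`, `b ≡ 1/12`, forecasting the constant.
Reference rates must be strictly positive.  This is the plain SVD
Lee-Carter; Poisson-likelihood and state-space variants, and age-specific
fits, are out of scope (no age structure in the data model).

## Excess and its confidence interval

Period rates are unweighted means of the annualized monthly CDRs over the
period's months — the `D*` adjustment has already equalized month lengths,
so no day-weighting is needed.  The annual estimate therefore decomposes
exactly as `(2·JanFeb + 4·Q2 + 3·Q3 + 3·Q4)/12`.  Q2 spans four months
(March–June) to capture the whole first pandemic wave; Q3 and Q4 are the
usual quarters.  Absolute excess is observed minus expected; relative excess
is the ratio to expected, in percent, and is invariant to rescaling all
deaths and exposures by a common factor.

Confidence limits use a residual bootstrap (B = 1000 by default, percentile
2.5/97.5, all randomness from one integer seed).  Reference-period residuals
are pooled within the unit, inflated by √(n/(n−p)) to undo the downward bias
of fitted residuals (p = 12, 13, or 22+N parameters for the three models),
and resampled with replacement to rebuild pseudo reference panels around the
fitted values; the baseline is refitted and the expected period rate
recomputed.  The excess interval is prediction-type: each replicate also
perturbs the observed period rate with resampled residuals (one per period
month), because the target-year counts carry sampling noise of the same
order as the baseline's estimation error — omitting that term would give
roughly 84% coverage instead of 95% at regional population sizes (∼10⁶).
Simulation places the empirical coverage near 93%; the remaining shortfall
comes from the pandemic-year months being more variable than the reference
months under Poisson noise (the pooled residuals cannot see that), and from
using the percentile method rather than BCa.  On a noiseless panel all
residuals vanish and the interval collapses to the point estimate with a
warning.  Lee-Carter replicates clip non-positive pseudo-rates to a tiny
positive floor before taking logs.

Rankings sort by absolute excess descending with a lexicographic unit-id
tie-break.

## Association and spatial clustering

Cross-unit association is ordinary least squares of excess on the covariate
plus the Pearson correlation with the exact two-sided t-test (n−2 df),
requiring at least three paired units and nonzero variance on both sides.
Permutation p-values would add nothing here and are not used.

Local Moran's I uses row-standardized symmetric weights supplied as an
adjacency edge list (no geometry is computed).  With deviations
`z_i = x_i − x̄` and `m2 = Σz²/n` (population variance — the convention under
which the mean of the local statistics equals the global Moran's I exactly),
`I_i = (z_i/m2) Σ_j w_ij z_j`.  Pseudo p-values come from conditional
permutation — the value at `i` held fixed, `k_i` of the remaining `n−1`
values sampled without replacement onto its neighbor slots — with the
two-sided rule `p = (1 + #{|I_perm| ≥ |I_obs|}) / (1 + permutations)`,
default 999 permutations.  Significant units are labelled HH/LL/HL/LH from
the signs of `z_i` and its spatial lag (threshold 0.05, configurable);
isolated units have undefined `I_i`, are flagged, and are excluded from the
global identity.  On spatially random fields the statistic flags close to 5%
of units at p < 0.05, as it should; no multiple-testing correction across
units is applied.

## Synthetic data generator

The generator emulates the structure of national-statistics inputs: for each
unit, intended monthly CDR
`(base + trend·(t − t₀))·s_m + wave(m)·[t = target]`, with seasonal factors
`s_m` averaging exactly 1 (default: winter-peaked cosine, ±10%, typical of
temperate-climate all-cause mortality), an additive linear trend (default
−15 per 100,000 per year, a steadily declining pre-pandemic mortality
level), base level ~1,200 per 100,000 and exposure 10⁶ person-years —
regional-scale magnitudes.  Waves are piecewise-linear ramps on the rate
scale (zero at start, peak amplitude, zero at end); single-month spikes
(start = peak = end) compose arbitrary monthly profiles.  Intended rates are
converted to expected death counts by *inverting* the month-length
adjustment, so the rate pipeline returns the intended CDR exactly on a
noiseless panel — this makes the closed-loop identities in the tests exact.
Counts are Poisson (the minimal noise model for death counts; overdispersion
is out of scope) or exact (`noise="none"`), all from a single seeded
generator.

Because the trend multiplies the seasonal factor, the monthly trend slope is
`β·s_m`; on a balanced panel the fitted common slope still equals `β`
exactly (the factors average to 1), but per-month residuals retain a small
`β(s_m−1)(t−t̄)` term.  Recorded ground truth: the seasonal level profile
`base·s_m`, the trend, period means of the injected wave intensity (the true
excess), and true infections/COVID deaths per 100,000.  True COVID deaths
default to 0.7 of true annual excess; true infections are COVID deaths
divided by an infection fatality rate of 1%.  Reported cases and deaths
multiply the truth by per-unit ascertainment and death-reporting fractions;
setting ascertainment inversely related to true burden reproduces the
ecological sign reversal (negative cross-unit correlation between reported
cases and excess) that faithful reporting never shows.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: overdispersed or autocorrelated count noise,
nonlinear secular trends (population ageing), age–sex structure, migration
or mid-year population revisions, reporting lags, and boundary changes.
Magnitudes are chosen to be realistic, not calibrated to any country's
series.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make Monte Carlo
bands tight while keeping the full suite fast: 500–600 simulated panels for
bias/coverage (B = 500), 80 units for the ecological correlation scenarios,
500 spatially random 5×6 fields at 999 permutations for the cluster
statistic's type-I rate, and 100 random instances for each brute-force
oracle equivalence check.  Noiseless-recovery assertions use relative
tolerance 1e-10; oracle-equivalence assertions 1e-8.  Ties in ranking break
lexicographically; degenerate inputs (constant fields, zero-variance
residuals, isolated spatial units, non-positive rates under a log model)
raise typed errors or collapse with a warning rather than returning NaNs.
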