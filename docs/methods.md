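# Methods

## Model and assumptions

The reference model treats √25(OH)D as Gaussian with a mean that is
linear in ten regressors — intercept, annual harmonics sin θ / cos θ
with θ = 2π(day−1)/365, semi-annual harmonics sin 2θ / cos 2θ,
t(BMI) = −1/√BMI and its square, a male-only one-sided quadratic
(t(BMI) − t(25))² for BMI < 25, and female-specific copies of the
annual harmonics — and a constant residual SD σ_ε. Everything else
follows in closed form:

* α-centile on the original scale: (max(0, ŷ + z_α σ_ε))²;
* quantile of a measurement y: Φ((√y − ŷ)/σ_ε).

Assumptions worth keeping in mind: the square-root transform is taken
to fully stabilise the variance (no BMI- or season-dependent spread);
the same σ_ε applies to every covariate combination; the model is
cross-sectional — it ranks a person against the population on a given
date and says nothing about that person's own trajectory across
seasons, which would require longitudinal data and a within-person
correlation below 1.

The bundled `PUBLISHED_MODEL` stores the reference coefficients exactly
as printed at their source precision (3–4 significant digits; the
low-BMI spline coefficient −1174 is printed with no decimals and is
correspondingly less precise). Reference worked examples validate at
that precision, so no re-derivation of extra digits is attempted.

## Conventions and numerical choices

* **Day convention.** Jan 1 ↦ day 1; angle 2π(day−1)/365. The calendar
  mapping is non-leap; Feb 29 is accepted and assigned index 60, so
  leap-year inputs are handled without error rather than rejected.
* **Centile clamping.** ŷ + z_α σ_ε can go negative for extreme α at
  high BMI; it is clamped at 0 before squaring (with a RuntimeWarning),
  since squaring a negative would silently break monotonicity in α.
* **BMI < 25 indicator** is strict. At BMI = 25 the regressor is zero
  under either convention, so this only matters for refits; the term is
  continuous with continuous first difference at the knot, verified by
  test.
* **α is a probability** in (0,1); percent inputs are rejected rather
  than divided by 100.
* **Seasonal extrema** are found by scanning integer days 1–365
  (matching calendar-date reporting) rather than solving the continuous
  stationarity equation; ties break to the smallest day. The
  coincidence of the male and female maxima on August 22 is confirmed
  by computation, not assumed — the acceptance script errors if the two
  argmaxima ever disagree.

## Refitting and model selection

Fits are OLS on √y via statsmodels, which also supplies per-coefficient
standard errors. σ_ε uses the unbiased denominator √(RSS/(n − k)) with
k the number of regression coefficients; at n ≈ 5000 the distinction
from the ML version is negligible. BIC is the Gaussian
profile-likelihood form n·ln(RSS/n) + k·ln(n) with additive constants
dropped and the variance parameter counted in k; only BIC differences
between candidates on the same data are consumed, so these conventions
cancel. Rank deficiency is detected by pivoted QR and reported with
the names of the collinear columns (a single-sex cohort with sex
interactions is the typical case). Missing-covariate rows are dropped
listwise with a logged count; missing response values are an error.

The default candidate set spans the determinants the model considers —
one vs two harmonics, the BMI terms, sex main effect, sex × season,
age and age × sex — as configuration, not as a claim to replicate any
particular historical search.

## Passing–Bablok calibration

The classic structural estimator: slope = shifted median of all
pairwise slopes (slopes equal to −1 discarded, coincident pairs
discarded, vertical pairs ranked as signed infinities, median offset by
K = #{slopes < −1}), intercept = median(y − slope·x), CIs from the
rank-based normal approximation with w = z·√(n(n−1)(2n+5)/18). Even
slope counts use the midpoint of the two central order statistics. No
installed package provides this estimator, so it is implemented here
and checked in the tests against an independent brute-force enumeration
of all pairwise slopes.

The estimator presumes positively related methods; data whose pairwise
slopes cluster at or below −1 push the shifted median off the end of
the slope list and are not a valid method comparison.

Calibration lines carry a `scale` tag (`original` nmol/L or `sqrt`);
applying a line to values declared on the other scale is an error, and
the sqrt-scale path in validation transforms, maps, and squares back.
The bundled immunoassay/LC-MS/MS line stores the published values
(intercept 8.71, slope 0.86, n = 125) on the original scale; the two
assays agree at the fixed point 8.71/(1 − 0.86) ≈ 62.2 nmol/L.

## Validation by quantile uniformity

If the model is correctly specified, predicted quantiles are
Uniform(0,1). The one-sample KS statistic uses the order-statistic
formula max_i max(i/n − u_(i), u_(i) − (i−1)/n) (cross-checked against
scipy's kstest). The CI on the KS statistic is a nonparametric
bootstrap percentile interval, B = 1000 resamples by default with a
fixed seed — labelled as such because an analytic band would be a
different (and composite-null) object. Histograms default to 20 equal
bins on [0,1]. Quantiles exactly 0 or 1 (possible only through
clamping) are nudged into the open interval before the KS formula.

## Synthetic cohorts

The generator emulates the covariate structure of a Swiss adult
population cohort: sex Bernoulli(0.493 male); BMI and age truncated
normals on [18, 40] and [35, 65] with SDs 4.12 and 8.5; measurement
day drawn by 12 configurable monthly weights (uniform by default) then
uniformly within the month; √25(OH)D = model mean + N(0, σ_ε), squared,
clamped at 0. A 3.9% fraction of rows is flagged as supplemented with
an additive sqrt-scale shift of +1.23 (≈ √66.05 − √47.58, the contrast
between supplemented and unsupplemented participants in the source
population) — a fixture choice so the inclusion filters have something
to exclude, not an estimate of supplementation pharmacology.

Because truncation at asymmetric bounds shifts the mean of a truncated
normal (location 25.61 would generate BMI averaging 25.93), the
generator solves for the location parameter so the *truncated* mean
equals the requested one; generated sample moments then match the
stated cohort moments directly. Sex and BMI are drawn independently;
any sex-specific BMI structure of real populations is not emulated
unless configured explicitly.

What passing tests on these cohorts show — and don't: parameter
recovery, σ_ε estimation, BIC behaviour and quantile uniformity are
exercised under the model's own data-generating process with realistic
covariate dispersion. They cannot detect misspecification present in
real data (assay drift, non-Gaussian tails, BMI-dependent variance),
and the replication-cohort fit statistics reported for the original
studies depend on data that are not deposited and are therefore not
reproduced here.

## Inclusion filters

`apply_inclusion_criteria` keeps rows with 35 ≤ age ≤ 65 and
18 ≤ BMI ≤ 40 (closed intervals, boundary-tested) and drops
supplemented rows unless asked to keep them; the exclusion log counts
rows per reason (a row can violate several) plus totals, and
kept + excluded always equals the input count.

## Problem sizes

Stochastic test batteries run at the sizes the analyses target:
parameter recovery at n = 5000 over 200 replicates, uniformity over
500 cohorts of n = 1000, calibration coverage at the 125-pair
comparison size over 200–300 replicates. The full suite runs in well
under a minute.

## Known limitations

* Latitude, ethnicity, diet and supplementation dose are outside the
  model; the reference coefficients are specific to latitude ≈ 46° and
  a Caucasian adult population.
* No individual-trajectory prediction (see assumptions above).
* Units are nmol/L throughout; no ng/mL conversion.
* The BIC search can only choose among the configured candidates; with
  the original data unavailable there is no guarantee the published
  structure would win on other cohorts.
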