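# Methods

This note documents the models, numerical choices and limitations of the
pipeline: what each stage computes, which parameters matter, and what the
synthetic studies do and do not demonstrate about real data.

## Chronology construction

**Detrending.** Each core's ring widths `w_t` (mm) are divided by a fitted
growth curve, giving a dimensionless ring-width index with mean ≈ 1. The
growth curve is Friedman's variable-span supersmoother: local linear fits at
three candidate spans (0.05, 0.2, 0.5 of the series length); per point, the
span with the smallest smoothed leave-one-out absolute residual is selected
(ties resolved toward the larger span, which favours smoother detrending
curves); the selected spans are themselves smoothed with the midrange span;
the final fit interpolates between the two bracketing span-level fits and is
passed once more through the tweeter span. Leave-one-out residuals come from
the hat-diagonal identity of linear smoothers, so no refitting is needed.
The `bass` parameter (0 by default, capped at 10) moves the selected span
toward the largest span by the factor `(r_best/r_woofer)^(10−bass)`.
Series shorter than 10 years are detrended by their own mean (flat line)
with a warning. Fitted values ≤ 0 are floored at `1e-6 × median width`
(warned) so the ratio index stays positive.

Ratio detrending (raw/fit) was chosen over differencing: it is the standard
dendro convention and keeps the index dimensionless around 1.

**Pre-whitening.** The detrended index of each core is pre-whitened
*before* averaging (matching the behaviour of standard chronology software;
whitening the averaged chronology instead is available via
`ChronologyConfig(prewhiten_per_core=False)`). The AR order p is selected by
AIC (`n·log σ̂²_p + 2p`) over 0..min(round(10·log₁₀ n), n−2), with
coefficients from Yule–Walker equations on *biased* (denominator-n)
autocovariances — the standard choice, and numerically essential: unbiased
autocovariances make high-order fits unstable on short cores and AIC then
overfits badly. Residuals are re-centred so the output mean equals the
input mean exactly, and are aligned to years p+1..n. Order 0 returns the
series unchanged; constant series are returned unchanged with a warning.

**Averaging.** Per year, available core indices are combined with Tukey's
biweight location: start at the median, scale S = MAD about the current
estimate, u = (v−m)/(c·S) with c = 9, bisquare weights (1−u²)² for |u| < 1,
iterated to |Δm| < 1e-8 (max 50 iterations). Fewer than 4 values fall back
to the median. Sample depth is recorded per year.

## Lagged regression scoring

Growth year t is paired with the 8 consecutive months ending at the end of
the growing season — month 8 (August) for northern-hemisphere sites, month
2 (February) for southern ones, whose window therefore spans two calendar
years; southern growth years are labelled by the year containing the
season's end (Schulman convention). The 8-month window *includes* the end
month; this reading covers the growing season plus the preceding months
where precipitation–growth correlations are expected.

A design row exists only where the response is non-missing and all 8 window
months are present — missing months drop the year rather than being
imputed. Before scoring, every product's design for a site is restricted to
the intersection of usable years across all products (pairwise-complete),
so all products are judged on identical data; this is asserted at fit time.

The score is un-adjusted R² from OLS of the (z-scored) response on an
intercept plus the 8 predictor columns (raw mm; R² is invariant to affine
rescaling of either side). Collinear columns are eliminated by pivoted QR
with relative tolerance 1e-10 and the reduced fit is reported with a
warning; a constant response makes R² undefined and excludes that site (for
*all* products, to preserve balance). Full-period fits require at least 20
observations (comfortably above the 10 = 8 predictors + intercept + 1
minimum).

Moving windows are 21 years long (odd, so the midpoint year is exact:
midpoint = first year + 10), stepped by 1 year, anchored to the calendar
years of the evaluation span (1901–2000 by default) regardless of a site's
own coverage, so midpoints align across sites: a complete span yields
midpoints 1911..1990. Windows with any missing design year are skipped
rather than fitted on fewer rows — with n = 21 and p = 8 the fit is already
heavily parameterised, and unequal n would make window R² incomparable.
Because designs are pairwise-complete, a skipped window is skipped for
every product of that site.

## Condorcet regional ranking

Each site contributes one ballot: products sorted by descending R², exact
ties sharing a rank (no jitter — exact float ties are meaningful only in
degenerate inputs, and jitter would break determinism). Pairwise tallies
count strict preferences only; ties count for neither side. The regional
winner must beat every other product head-to-head; the loser must lose
every contest. A majority cycle is reported explicitly (`winner = none`,
`used_fallback = true`) together with Copeland scores (pairwise wins minus
losses) for downstream tie-breaking, rather than silently electing a
fallback. Regions with fewer than 5 ballots are flagged `low_n`. Regional
aggregate R² uses the arithmetic mean (median available as an option).

## Synthetic studies

The generator emulates the study ingredients with known structure:

- **Truth precipitation**: per site and month,
  `P = seasonal_mean[month] × LogNormal(unit mean, cv = seasonal_cv)`;
  default seasonal means are a temperate summer-maximum regime (45–90
  mm/month) with cv 0.4.
- **Products**: `P_k = P × exp(ε)`, `ε ~ N(0, sd_k)`, independent across
  products, sites and months; defaults sd = (0.25, 0.5, 1.0), optionally
  region-specific. Multiplicative lognormal error keeps products positive
  and scales error with precipitation magnitude, matching precipitation's
  skewed non-negative nature.
- **Growth**: site signal `g_t = Σ_j β_j z_jt + η_t` with z the truth
  precipitation standardized per calendar month across years (so β is
  scale-free and R² targets are interpretable), β defaulting to 8 weights
  rising toward the growing season (Σβ² ≈ 0.14), and η stationary AR(1)
  (φ = 0.3, innovation sd 0.3). Core widths are
  `2.0·exp(−0.03·age) × exp(g_t + N(0, 0.25))`, strictly positive, with
  start years staggered uniformly over the first third of the span to
  exercise ragged-edge averaging.
- **Greenness**: the same response model without age trend or replication;
  a fraction (default 0.1) of cells is missing at random and sites are
  retained only at ≥ 50 % non-missing years. 20 % of sites are southern-
  hemisphere by default, exercising the cross-year window.

One `numpy` Generator seeded from `config.seed` drives a study; the draw
order is documented in `simulate.py`, and identical configs reproduce
studies bit-for-bit.

What the synthetic studies do **not** emulate: spatial autocorrelation among
sites, product error geography tied to station density, species mixtures,
dating error, or the nonstationary climate response of real trees. Passing
recovery tests shows the pipeline orders product quality correctly when the
generative assumptions hold; it says nothing about which real product is
best anywhere.

A note on fidelity: because widths are `exp(g)`, a large signal variance
makes the width–signal relation visibly convex and caps the *linear*
correlation between a chronology and its planted signal (the log index
correlates far higher). Recovery tests therefore use moderate signal
variance, where the exponential is near-linear.

## Problem sizes and numerical checks

Recovery experiments use 100 sites × 80 years × 3 products per replicate
(20 replicates in the test suite, 10 in the acceptance script), which
recovers the planted ordering essentially always while keeping a full run
in tens of seconds. Null calibration uses 200 signal-free sites and checks
the mean R² against p/(n−1) within four standard errors of the Beta null
distribution of R². Oracle-equivalence checks compare the biweight mean,
the Condorcet winner and OLS R² against independently coded brute-force
references (tolerances 1e-6, exact, and 1e-10 respectively).

## Known limitations

- The supersmoother uses symmetric truncated windows and three fixed spans;
  it is a faithful variable-span CV smoother but not a line-for-line port
  of any particular implementation, so fitted values can differ in the
  third decimal from other supersmoother codes.
- Greenness series are not pre-whitened by default (flag available); only
  chronologies are.
- AR order selection supports AIC (default) and BIC only.
- RWL parsing requires gap-free, terminator-closed series; headers and
  comment lines are not supported.
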