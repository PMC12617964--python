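# Methods

## Trend model and the MID statistic

The trend stage fits, by ordinary least squares,

    RSV_i = β₀ + Σ_{j=1..4} β_j B_j(t_i) + ε_i

where t_i is the numeric-year time of month i and {B_j} is a cubic B-spline
basis with 4 degrees of freedom.  Conventions (the "R `bs()`" family of
conventions, stated explicitly because several coexist):

* **Time axis.**  Month i maps to `year + (month − 0.5)/12`, placing each
  month at its midpoint in fractional years.  Any affine time scale gives
  the same fitted curve; this one makes "per year" derivatives literal, so
  dividing by 12 converts exactly to per-month units.
* **df counts spline columns only.**  The intercept is a separate model
  term; the full order-4 spline space on the fitted range has 5 B-spline
  columns and the constant-carrying first column is dropped.
* **Knots.**  df − degree = 1 interior knot at the median observation time
  (quantile placement); boundary knots at the first and last month.
  Evaluation outside the boundary knots is an error, not extrapolation.

The mean instantaneous derivative is

    MID = (1/12) · mean_i s′(t_i)

with s′ the analytic derivative of the fitted spline (differentiated basis
times coefficients), evaluated at the observed months only.  Positive MID =
rising interest, in RSV units per month.  Because s′ is linear in the
coefficients and the coefficients linear in the data, MID is a linear
statistic of the observations; its bootstrap is therefore exact to
vectorize (see Numerical choices).

**Residual bootstrap.**  Residuals are resampled with replacement, added to
the fitted values, and the model refitted; 95% CI = 2.5/97.5 percentiles of
the bootstrap MIDs, and the two-sided p-value is

    p = max( 2·min( P(MID* ≤ 0), P(MID* ≥ 0) ),  2/(B+1) )

the standard percentile-bootstrap sign test with a floor that prevents a
literal zero.  Residuals are resampled raw; a leverage adjustment
(r_i / √(1−h_ii)) is available behind a flag, default off — with n ≈ 68
and 5 parameters the leverages are small and the adjustment widens CIs
only slightly.  Assumptions: independent, exchangeable residuals.  Monthly
search series are mildly autocorrelated in reality; a block bootstrap is a
deliberate non-goal, and the calibration results below apply to the
independent-noise setting the generator produces.

**Falsification contrast.**  The control series (a topic with no expected
trend) is analyzed with identical spline and bootstrap settings; the
verdict is a rule on the two p-values at α (default .05): target
significant and control not ⇒ "trend specific to target"; neither ⇒ "no
specific trend"; both ⇒ "nonspecific rise; confounding not excluded".  No
new statistic is invented.

## Seasonality

RSV values are grouped by calendar month and tested with the tie-corrected
Kruskal–Wallis H; p comes from the chi-square approximation with
(months present − 1) df.  At study scale (68 months ⇒ groups of 5–6) the
approximation is serviceable and matches standard software; a seeded
Monte-Carlo permutation p (`n_permutations`) is available as a check.  Two
degenerate rules: a calendar month with fewer than two observations is an
error naming the month, and an all-tied series returns H = 0, p = 1 (the
tie correction term degenerates to 0/0 there, and no evidence against the
null is the only sensible reading).

## Correlation screen

Environmental series are preprocessed in this order: interior missing runs
linearly interpolated between flanking observations; series missing an edge
month, more than 30% of cells, or constant after filling are excluded with
machine-readable reasons (`edge-missing`, `excessive-missingness`,
`zero-variance`).  The 30% cutoff generalizes the practice of interpolating
isolated gaps while dropping wholly unavailable parameters; it is a
package choice, there being no established threshold.

Both RSV and each parameter are z-standardized (sample SD, n−1).  For the
rank correlation this is provably a no-op (and the suite tests that); it is
retained because the standardized series are exactly what the DTW stage
consumes, keeping one preprocessing path.

Spearman's rho is the Pearson correlation of tie-averaged ranks, with
perfect concordance/discordance returned as exactly ±1.  The p-value uses
the t approximation t = rho·√((n−2)/(1−rho²)) on n−2 df, two-sided —
adequate at n = 68; a Monte-Carlo permutation p is available for small n.
At |rho| = 1 the t statistic is unbounded and p is reported as the smallest
positive float rather than 0.  Tiers: p < .05 and p < .001.  No multiple
testing correction is applied, matching common reporting practice in this
literature; the report records the number of tests so readers can apply
their own.

## DTW alignment

Unconstrained symmetric dynamic programming,
D(i,j) = d(i,j) + min(D(i−1,j), D(i,j−1), D(i−1,j−1)), local cost
d = |xᵢ − yⱼ| on standardized series.  This is the textbook default; no
window, no slope constraint, and no path-length normalization (a
normalized distance and a squared cost are available behind flags — all
series here share one length, so normalization changes ranks only via
path-length differences).  Backtracking breaks ties diagonal-first, then
vertical, then horizontal, making paths reproducible; the distance is
tie-invariant.  Only parameters significant in the Spearman screen are
aligned, and ties in distance are broken by parameter name so the ranking
is independent of panel order.

## Synthetic data generator

The generator emulates a study window of 68 months from 2018-12: an RSV
series with a known trend, and a 21-parameter environmental panel (4
linked, 17 null by default — roughly the proportion of screen-significant
parameters such a study reports).

* **Trend shapes.**  `none` (flat), `linear` (exact slope
  R/(n−1) per month), and `smooth_rise`: a logistic ramp in scaled time,
  rescaled to span exactly `trend_total_rise` (default 30 RSV units ⇒ mean
  rate ≈ 0.45 RSV/month).  The recorded `true_mid` is the analytic mean
  derivative of the noiseless trend at the observed months, divided by 12 —
  the same functional the estimator targets.  The logistic steepness
  (default 4) was fixed by a deterministic design computation: the df = 4
  spline's projection of the noiseless k = 4 ramp has a MID within 1.2% of
  the analytic truth, so recovery experiments measure estimation error, not
  irreducible approximation bias; steeper ramps leave the 4-df model's
  resolving power and would conflate the two.
* **Noise** is iid Gaussian (default SD 8 RSV units, giving spline fits
  with adjusted R² around 0.5–0.65, typical of published search-interest
  trends); values are clipped to [0, 100] after noise, mirroring RSV
  normalization, while truth is computed pre-clip so it stays analytic.
* **Seasonality** is a sinusoid in calendar month (default amplitude 0).
  `true_mid` is defined on the trend component alone; the seasonal term's
  derivative averages to ~0 over whole cycles.
* **Linked environmental series** mix the standardized noiseless RSV
  signal — shifted so the environmental series *leads* RSV by `link_lag`
  months (default 1, a delayed-impact reading), edges repeated — with
  independent noise: x = sign·√λ·z + √(1−λ)·ε, so `link_strength` λ
  (default 0.6, producing realized |rho| ≈ 0.6 at study scale) is the
  fraction of variance from the shared signal.  Null series are pure
  noise.  An affine display transform (×10 + 50) makes CSVs look like
  measured data; every downstream statistic is invariant to it.
* **Missingness** masks interior cells at `missing_rate` (default 0.02,
  sparse like real agency data), never the first or last month, matching
  the interior-only interpolation rule.
* **Determinism.**  Each series draws from its own RNG stream keyed by
  (seed, series index), so adding series never perturbs existing ones and
  identical configs are bit-identical.

What the generator does **not** emulate: Google-Trends sampling
renormalization quirks, autocorrelated noise, spatial correlation between
geographies, and heavy-tailed pollutant distributions.  Passing
calibration tests therefore demonstrate correctness of the statistical
machinery under clean conditions, not robustness of the study design to
those real-data features.

## Numerical choices

* MID is linear in the data (v·y for a fixed weight vector), so the
  bootstrap refit is computed for all iterations at once via the
  pseudoinverse of the fixed design matrix — exactly equivalent to
  refitting per iteration, at a tiny fraction of the cost.
* Adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) with p = 4 spline columns; a
  zero-variance response flags R² undefined rather than emitting NaN.
* Percentile CIs may in pathological resamples exclude the point estimate;
  only ci_low ≤ ci_high is guaranteed.
* Derivatives are evaluated analytically from the differentiated B-spline
  basis, not numerically.
* Reports serialize with sorted keys and fixed float repr, so a fixed
  seed reproduces byte-identical JSON.

## Problem sizes

The test suite and acceptance script run simulations at: 200 replicates ×
500 bootstrap iterations for bootstrap calibration and CI coverage; 200
replicates for MID recovery and DTW ranking recovery; 500 replicates for
Kruskal–Wallis and Spearman null calibration (120 and 68 months
respectively); 200 random small instances (n·m ≤ 36) for the DTW
enumeration oracle; and a 6-geography, 68-month full-pipeline determinism
check.  These sizes put Monte-Carlo standard errors well inside the
asserted calibration bands while keeping the whole suite in the
tens-of-seconds range.

## Known limitations

* The bootstrap assumes exchangeable residuals; autocorrelation in real
  monthly series would make the type-I error anticonservative.
* The chi-square Kruskal–Wallis p is approximate at 5–6 observations per
  month; use the permutation option when that matters.
* DTW distances are comparable only across series of equal length and
  identical standardization; no significance measure is attached to them.
* The Spearman screen is marginal — co-pollutant confounding is untouched
  (partial correlations are a non-goal).
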