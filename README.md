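# infotrend

Analysis pipeline for **infodemiology time series**: monthly Google-Trends
style relative search volume (RSV, normalized 0–100) for a health topic in a
region, screened against a panel of monthly environmental parameters
(meteorology and air pollutants).

The package answers four questions a search-interest study asks:

1. **Is interest trending?**  An ordinary least-squares fit of RSV on an
   intercept plus a cubic B-spline basis (4 df) of the numeric-year time
   variable; the trend statistic is the **mean instantaneous derivative
   (MID)** — the fitted spline's first derivative s′(tᵢ) evaluated at every
   observed month (RSV units per year), averaged, and divided by 12:

       MID = (1/12) · (1/n) · Σᵢ s′(tᵢ)   [RSV units per month]

   A residual bootstrap (default 1000 iterations) supplies the 95%
   percentile CI and a two-sided p-value.  A *falsification control* — a
   second topic expected to show no trend — is analyzed identically and
   juxtaposed: a significant target trend with a flat control argues
   against nonspecific drift (e.g. rising internet use).
2. **Is interest seasonal?**  RSV values grouped by calendar month,
   compared with the tie-corrected Kruskal–Wallis H test (chi-square p;
   Monte-Carlo permutation p optional).
3. **Which environmental parameters co-move with interest?**
   Interior missing cells are linearly interpolated (series missing edge
   months or >30% of cells are excluded), series are z-standardized, and
   each parameter is screened with the Spearman rank correlation, reported
   in two tiers (p < .05, p < .001), without multiplicity adjustment.
4. **Which of those track interest most closely in time?**  Dynamic time
   warping (symmetric step pattern, |·| local cost, no window) between
   standardized RSV and each screened parameter; the smallest DTW distance
   is the strongest temporal alignment.

Because real RSV exports are retrieval-date dependent, the package includes
a first-class **synthetic-data generator** with analytic ground truth
(trend shape and true MID, linkage strength/sign/lag per environmental
series, masked-cell ledger), so the entire pipeline is testable end to end.

## Worked example

```python
import infotrend as it

cfg = it.SyntheticConfig(seed=11)              # 68 months, smooth rise
rsv, truth = it.generate_rsv(cfg)
est = it.bootstrap_mid(rsv, n_boot=1000, seed=1)
print(f"true MID      = {truth.true_mid:.3f} RSV units/month")
print(f"estimated MID = {est.mid:.3f}  "
      f"(95% CI {est.ci_low:.3f} to {est.ci_high:.3f}, p = {est.p_value:.4f})")

panel, _ = it.generate_env_panel(cfg, rsv)
screen = it.correlate_panel(rsv, it.preprocess_panel(panel))
ranking = it.rank_alignment(rsv, it.preprocess_panel(panel), screen)
```

prints

```
true MID      = 0.445 RSV units/month
estimated MID = 0.348  (95% CI 0.220 to 0.485, p = 0.0020)
```

The generator's noiseless logistic trend rises 30 RSV units over 68 months
(true mean rate 0.445/month); with month-to-month noise of 8 RSV units this
particular seed estimates 0.348 with a CI that covers the truth and a
p-value at the bootstrap floor — a clearly significant rising trend.  The
correlation screen flags the four genuinely linked panel series at the
p < .001 tier (rho ≈ +0.63 to +0.66) and the DTW ranking places a linked
series first (distance 22.4 in accumulated z-units).

The same stages are available as shell commands:

```bash
infotrend simulate --seed 5 --out-rsv rsv.csv --out-env env.csv
infotrend trend --input rsv.csv --n-boot 1000 --seed 1 --out trend.json
infotrend seasonality --input rsv.csv --out season.json
infotrend correlate --rsv rsv.csv --env env.csv --out table1.csv
infotrend dtw --rsv rsv.csv --env env.csv --screen table1.csv --out dtw.csv
infotrend run --synthetic --out-dir results/   # full pipeline, one report
```

Input CSVs are wide panels: a `date` column in ISO `YYYY-MM`, one column
per variable, empty cells for missing months.

## Scope

The package covers the statistical pipeline only.  Retrieving Google
Trends data, categorizing rising queries, and scoring web-page quality or
readability are editorial/manual steps outside its scope.
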