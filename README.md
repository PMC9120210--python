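# capreosex

Statistical tools for analysing sex-ratio variation in roe deer
(*Capreolus capreolus*) offspring: does the sex ratio at birth approach the
1:1 equilibrium predicted by Fisher's principle, and do weather conditions
before and during gestation shift it?

The package implements two complementary analytical chains:

* **Between-population meta-analysis.** Each published data set reports a
  proportion of female offspring `pf` out of `N`. This is converted to a
  standardized log-odds effect size (Chinn's conversion)

  ```
  d = ln(OR) / (π/√3),    OR = pf / (1 − pf),
  ```

  with sampling variance `var(d) = (1/n_f + 1/n_m) · 3/π²`; `d < 0` means a
  male-biased sex ratio. Effect sizes are pooled with inverse-variance
  fixed-effect weights or a random-effects model (DerSimonian–Laird or REML
  estimate of the between-study variance τ²), heterogeneity is quantified by
  Cochran's Q and both the Q-based and τ²-based I², exact Clopper–Pearson
  intervals accompany every proportion, funnel-plot data with pseudo-CI
  contours support publication-bias checks, and a spatial meta-regression
  relates `d` to latitude, latitude², longitude and longitude². Two
  study-level tables transcribed from the published literature compilation
  (25 references; 15 secondary-sex-ratio sites with WGS84 coordinates) are
  bundled, together with the systematic-review screening filters (offspring
  ≤ 6 weeks old, N ≥ 50, de-duplication) and an auditable exclusion log.

* **Within-population climate-window analysis.** For individual tagging
  records (sex, birth year, elevation), candidate covariates are means of
  monthly temperature or precipitation over every contiguous window between
  June(t−1) and February(t) — 45 windows. Temperatures are corrected to each
  animal's elevation with the standard environmental lapse rate
  `Tcor = T − 0.65 · hasl/100`. Each window's binomial GLM

  ```
  logit P(female) = a0 + a1·x + a2·x²
  ```

  is compared against an intercept-only null by AICc; Akaike weights are
  normalized over the null plus all windows, per elevation class
  (<250, 250–500, 500–750, ≥750 m). A synthetic-data module generates
  weather, offspring and study tables with planted effects so the entire
  chain is testable without the (unreleased) raw tagging data.

## Worked example

```python
from capreosex import load_site_table, random_effects_pool, heterogeneity, meta_regression

sites = load_site_table()                      # 15 secondary-sex-ratio data sets
pooled = random_effects_pool(sites, "DL")
print(round(pooled.pooled_d, 4), round(pooled.ci_low, 4), round(pooled.ci_high, 4))
# -0.0453 -0.0671 -0.0235
print(round(heterogeneity(sites, "REML")["i2_tau"], 2))
# 0.75
print(round(meta_regression(sites).coefficient("latitude"), 3))
# -0.107
```

The pooled effect size of −0.05 (95% CI −0.07 to −0.02) is small but its
interval excludes zero: across 23,420 offspring from 15 European data sets
the sex ratio at birth is male-biased. The τ²-based I² of 0.75% indicates
essentially no between-study heterogeneity, and the latitude coefficient
(−0.107, n.s.) traces a weak U-shape: female-biased ratios at the southern
and northern range margins.

More narrative scripts live in `examples/` (effect sizes, screening,
climate-window scan, synthetic parameter recovery); each prints its results
with a short interpretation. A thin CLI mirrors the library:

```
capreosex meta --model random --method DL --ratio-type S
capreosex simulate --seed 7 --out sim/ && capreosex scan --offspring sim/offspring.csv --weather sim/weather.csv
```

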