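# Methods

## Effect sizes for single proportions

The unit of the between-population analysis is a data set reporting
`n_f` female and `n_m` male offspring. The proportion female
`pf = n_f/(n_f + n_m)` is mapped to a standardized effect size
`d = ln(pf/(1−pf)) / (π/√3)`: the log odds ratio divided by the standard
deviation of the logistic distribution, which places a single-proportion
log-odds on the familiar standardized-mean-difference scale. `d = 0` is
parity; `d < 0` is a male bias.

No published variance formula accompanies this conversion for single
proportions, so the package uses the standard logit variance
`1/n_f + 1/n_m` rescaled by `3/π²`. This choice reproduces the published
pooled confidence intervals on the bundled tables (see the acceptance
script), which is the operational test of its adequacy. Zero cells are
refused rather than continuity-corrected: with the screening floor of 50
offspring and observed proportions between 0.43 and 0.60, a zero cell
cannot arise in real tables, and silently shifting `d` for synthetic edge
cases would be worse than an explicit error.

Proportion-scale uncertainty uses the exact Clopper–Pearson interval
(beta-distribution quantiles), which is conservative by construction;
d-scale intervals use the normal approximation `d ± 1.96·se`. The dual
usage is deliberate: exact inference where the binomial structure is
available, normal theory where effect sizes are pooled.

Published tables print `pf` to two decimals. Counts are reconstructed as
the nearest integer to `pf·N` (ties away from zero); a warning fires if the
reconstruction cannot round back to the printed value. All downstream
results on the bundled tables therefore inherit a ±0.005 quantization of
`pf`, which is well inside every tolerance used in the tests.

## Meta-analysis

Fixed-effect pooling uses inverse-variance weights. The random-effects
model estimates the between-study variance τ² either by the
DerSimonian–Laird moment estimator (primary; closed form, truncated at
zero) or by REML. REML maximizes the restricted log-likelihood by bounded
Brent search on [0, max(10·var(d), 10·max var_i)] with tolerance 1e−10 and
an explicit boundary check at τ² = 0; for the bundled secondary table the
restricted likelihood is nearly flat near zero, so any REML implementation
lands within ~1e−5 of zero and the τ²-based I² within a few tenths of a
percentage point. Both estimators were cross-checked against an independent
reference implementation on small fixtures and agree to at least six
decimals.

Heterogeneity is reported both ways: `I²_Q = max(0, (Q−df)/Q)·100`, which
truncates to zero whenever Q ≤ df, and the τ²-based
`I²_τ = 100·τ²/(τ² + s²)` with `s²` the typical within-study variance
(Higgins: `s² = (k−1)·Σw / ((Σw)² − Σw²)`). The τ²-based flavour with REML
is what the package reports by default, because it remains informative in
the near-homogeneous regime where the Q-based index collapses to 0.

The spatial meta-regression of `d` on latitude, latitude², longitude and
longitude² is unweighted ordinary least squares by default — mirroring a
plain GLM treatment of effect sizes — with an inverse-variance weighted
option. With k = 15 sites and 5 parameters, coefficients are sensitive to
the ±0.005 proportion quantization; the latitude coefficient on the
bundled table is −0.107 against a published −0.121, within the propagation
of that rounding. Confidence multipliers are normal (1.96) throughout
rather than Knapp–Hartung, matching the published interval widths.

Funnel data export one (d, se) point per study and pseudo-confidence
contours at 90/95/99% fanning around the fixed-effect estimate; rendering
and formal asymmetry tests beyond this export are out of scope.

## Screening

Filters run in a fixed order — oldest-offspring age (> 42 days excluded),
sample size (< 50 excluded), then duplicates, inaccessible references and
ambiguous reporting — and every row receives exactly one logged decision,
so category counts are reproducible functions of the documented order.
"Six weeks" is operationalized as exactly 42 days, and both boundaries
keep the boundary value (age 42 kept, N = 50 kept). Strict mode excludes
rows with unreported age or ratio type; lenient mode keeps them with a
warning. Duplicate merging sums counts over rows sharing a merge key,
joins ids with `+`, and refuses to mix prenatal with secondary ratios.

## Climate-window scan

The window axis is fixed to the nine calendar months June(t−1) through
February(t) — rut through embryo implantation and late gestation —
aggregated per birth year, not per individual birth date (the tagging data
carry year-level resolution only; windows relative to individual birth
dates would imply a precision the data do not have). All 45 contiguous
windows are enumerated; each covariate is the arithmetic mean of monthly
values over the window, and temperature covariates are corrected to the
individual's elevation by the standard environmental lapse rate of
0.65 °C/100 m before entering the model.

Each window model is a binomial GLM `logit P(female) = a0 + a1·x + a2·x²`
fit by IRLS (statsmodels, tolerance 1e−8, at most 50 iterations), with the
covariate mean-centered before squaring. Centering reduces the x/x²
collinearity and makes AICc *differences* invariant to additive covariate
shifts, a property the tests assert. Diverging coefficients (|β| > 30) are
treated as separation and raised as errors, as are single-sex subsets and
rank-deficient designs. Model comparison uses AICc
(`AIC + 2p(p+1)/(n−p−1)`; plain AIC by flag) against an intercept-only
null on the same subset, and Akaike weights are normalized over the null
plus all 45 windows. Ties on AICc break toward the wider, then
earlier-opening window. The scan runs per height class (<250, 250–500,
500–750, ≥750 m; half-open intervals so every elevation maps to exactly
one class; classes under 200 records are skipped with a warning), and a
consensus window minimizes the summed within-class AICc rank. The
classical twelve-covariate model (temperature and precipitation for
Jan/Feb/Mar of the birth year and May/Jun/Dec of the preceding year,
linear terms only) is provided for comparison.

A known and deliberate limitation: selecting the minimum AICc over 45
heavily correlated candidate windows is anti-conservative. Under a true
null, the best window's improvement is the maximum of ~45 correlated
χ²₂-distributed deviance drops against an AICc penalty of ≈ 4, so some
window spuriously beats the null in the majority of realizations (in the
package's own null simulations the intercept-only model retains the top
Akaike weight in roughly 30% of replicates). This is the same multiplicity
problem that motivates randomization tests in dedicated window-scanning
software; raw Akaike weights from a scan should be read as a relative
ranking of candidate periods, not as calibrated evidence against the null.
Randomization-based calibration is out of scope here.

## Synthetic data

The generators exist to close the loop: plant known parameters, run the
pipeline, recover them. Monthly temperature is Gaussian around a
temperate central-European climatology (per-month means from ~0.5 °C in
January to 19 °C in July; year-to-year sd of monthly means ≈ 1.5 °C);
precipitation is Gamma with moment-matched mean/sd (non-negative,
right-skewed). Defaults mirror the long-term tagging programme the
individual-level analysis targets: 48 annual cohorts (1972–2019), 260
offspring per year (~12,500 total), elevations mixed over the four height
classes (35/35/20/10%), tagging ages from a rounded Normal(8.4, 2.5)
clipped to [0, 42] days, baseline proportion female 0.48, and a planted
quadratic effect of the Oct(t−1)–Feb(t) mean temperature with
a1 = 0.019 and a2 = 0.08 — the quadratic term sized so the planted effect
spans roughly half a logit over the observed range of the centered
covariate (about ±2.5 °C of year plus within-class elevation variation).
Synthetic study tables draw true effects `d_i ~ Normal(μ_d, τ²)`
(heterogeneity planted on the d scale, exactly as the random-effects model
assumes), invert the Chinn conversion to proportions, and draw binomial
counts; degenerate all-of-one-sex draws are redrawn.

What the generators do **not** emulate — and hence what passing tests do
not certify about real data: temporal autocorrelation and spatial
structure in weather (months and sites are independent), elevation-
dependent climatology beyond the lapse-rate shift, maternal effects (age,
body mass, litter structure), and non-uniform tagging effort across years
and elevations. Recovery results on synthetic data show the estimators are
correct under their own assumptions, not that those assumptions hold in
the field.

All randomness flows through numpy Generators keyed by
`(seed, purpose)`; identical seeds give bit-identical outputs on one
platform, and results are stable at double precision (last-ulp differences
across BLAS builds can perturb IRLS iterates, but all tested quantities
are asserted at tolerances far above that).

## Problem sizes used in the shipped checks

The bundled tables are analysed at full size (15 and 25 rows; these
analyses are instantaneous). Simulation-based checks use 20 replicates of
~80,000 offspring (four height classes of ~20,000) for window recovery, 50
replicates at the default ~12,500 offspring for null calibration, 200
replicates of k = 40 studies for meta-analytic parameter recovery, and
2,000 draws per condition for exact-interval coverage — sizes at which the
Monte-Carlo error of each asserted quantity is comfortably below its
assertion tolerance.
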