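# Methods

## Study-level model

Each published study contributes an effect point with a 95% CI on its
natural reporting scale: hazard ratios (HR) and ratios of medians for the
FES-heterogeneous vs all-FES-positive contrast, per-group median PFS in
months, odds ratios for dichotomized baseline SUVmax, and standardized mean
differences (SMD) for continuous baseline SUVmean. All ratio-scale endpoints
are analysed on the natural-log scale; the SMD stays on the identity scale.
The endpoint tag on each record selects the transform — no caller ever
passes a scale flag.

**SE reconstruction.** A Wald CI on the ratio scale implies
`se = (ln hi − ln lo) / (2 z)` with `z = Φ⁻¹((1+level)/2)` computed from the
normal distribution (1.959964 at 95%), not hard-coded, so arbitrary levels
work. The reconstruction uses only the CI width and is invariant to common
rescaling of point and bounds (a tested property).

**Unbounded upper limits.** A survival curve that never falls to the bound
yields a CI like "4.8 to ∞". The unbounded limit is a first-class value
(IEEE infinity) through ingest and serialization (empty cell or `Inf`), and
is resolved for pooling by *symmetric imputation on the log scale*:
`hi = exp(2 ln point − ln lo)`. Symmetry is imposed on the log scale rather
than the raw scale because that is the scale on which pooling operates; the
composition then collapses to the one-sided formula
`se = (ln point − ln lo)/z` (a tested identity).

**Ratio of medians.** The two arms are distinct patient groups, so the
delta-method log-ratio variance is the sum of the two log-median variances
(independence assumption, documented here; any within-study dependence
would make this SE conservative is not modelled). The Wald CI reported for
the ratio can therefore differ from a CI printed in an original study,
which may derive from patient-level resampling.

**SMD.** Hedges-corrected g: Cohen's d with pooled SD shrunk by
`J = 1 − 3/(4(n₁+n₂−2)−1)`, variance `(n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))`.

**Odds ratio.** Woolf log-SE `sqrt(1/a+1/b+1/c+1/d)`; a zero cell triggers
the Haldane–Anscombe +0.5-to-every-cell correction, flagged on the result;
an all-zero row or column is an error, not a number.

## Pooling and heterogeneity

Fixed-effect: inverse-variance weights `w = 1/se²`, pooled mean `Σwθ/Σw`,
CI `θ̂ ± z/√Σw`, back-transformed for log-scale endpoints. Cochran
`Q = Σw(θᵢ−θ̂)²` with `df = k−1`, p from the upper χ² tail, and
`I² = max(0,(Q−df)/Q)·100`. Random-effects adds the DerSimonian–Laird
moment estimate `τ² = max(0,(Q−df)/C)`, `C = Σw − Σw²/Σw`, to every study
variance. The estimator sits behind a single function (`dl_tau2`) and is
swappable; DL was chosen as the standard moment estimator for small
meta-analyses. When Q < df, τ² truncates to zero and REM coincides with FEM
by construction — which is why the package reports 18.9 months for both
models on the all-FES-positive median column even though the source table
prints 18.8 for its (unnamed) random-effects estimator. All internal values
are full precision; rounding happens only at presentation.

Single-study input is legal for FEM: the pool degenerates to that study's
point and Wald CI, and the heterogeneity p is NaN rather than a fabricated
verdict. No significance threshold is hard-coded anywhere; tests and
p-values are reported as (statistic, p) pairs.

## Publication-bias diagnostics

Funnel coordinates are (log effect, log-scale SE) pairs sorted by SE with
the FEM pooled point as reference line. The Begg–Mazumdar test correlates
the standardized deviates `tᵢ = (θᵢ−θ̂)/√(vᵢ−1/Σw)` with the variances
`vᵢ`; the `1/Σw` subtraction accounts for θ̂ being estimated from the same
data. When that difference degenerates numerically (vᵢ ≤ 1/Σw) it is
floored at 1e-12 with a warning. Kendall's tau-b handles ties, which arise
naturally when SEs reconstructed from rounded CIs coincide. The two-sided
p-value is exact for k ≤ 8 — from the inversion-count null distribution of
the concordance statistic S when the data are untied, or full enumeration
of the ≤ 40,320 orderings when tied — and otherwise uses the tie-corrected
normal approximation with continuity correction. At k = 8 the two p-values
never differ by more than 0.013 over the entire untied support. Effectively
identical effects leave the deviates undefined; the test returns tau 0 with
an all-ties flag instead of manufacturing a ranking.

## IPD survival analysis

A lesion is FES-positive iff SUVmax ≥ threshold (boundary inclusive;
"at least 1.8"); a patient with ≥ 1 negative lesion among positives is
heterogeneous, and with no positive lesions all-negative. The survival
contrast is all-FES-positive vs *not*-all-positive: at a high threshold a
patient whose every lesion falls below it has (at least) one FES-negative
lesion and lands in the non-all-positive arm, consistent with the
observation that raising the threshold grows the heterogeneous group.

Kaplan–Meier estimation is delegated to lifelines (product-limit estimator,
Greenwood-style variance with the log(−log) transform, median CI in the
Brookmeyer–Crowley style); an undefined median (curve never reaches 0.5, or
no events) is `None`, never a sentinel number.

The Cox model is a purpose-built single-parameter solver because only a
binary covariate is needed and its full numerical contract matters:
Newton–Raphson from β = 0 on the **Efron** partial likelihood (monthly
resolution PFS makes ties common), convergence at |score| < 1e-8, at most
50 iterations, steps damped to ±2 per iteration. A monotone likelihood
(separated groups) is flagged — detected when |β| exceeds 10 or the
information degenerates — and reported with an infinite SE and a one-sided
unbounded CI rather than a spurious "converged" estimate. Tests pin the
solver to a brute-force grid maximizer of the explicit partial likelihood
(|Δ log HR| < 1e-4 over 200 random small datasets), to lifelines'
`CoxPHFitter`, and to the log-rank score at β = 0.

The threshold sweep builds its grid by integer stepping
(`round((hi−lo)/step)+1` points) to avoid floating-point drift at 0.1
increments — the primary grid 1.8–4.0 has exactly 23 thresholds. Degenerate
splits (empty arm, no events) yield an undefined Cox entry with a reason
string; the sweep never aborts. The all-positive arm's size is
nonincreasing in the threshold by set containment, a property-tested
invariant.

## Synthetic cohorts

The IPD generator emulates the *structure* of the pooled three-study FES
cohort, with every default chosen from the cohort's published summary
statistics: 101 patients; heterogeneity probability 0.25 (25/101); lesion
count per patient `1 + NegBin(r=1.8, mean=7.69)`, calibrated by quantile
matching to median 7 and IQR 4–12 (mean 8.69 ⇒ ≈ 878 lesions per 101
patients); positive-lesion SUVmax log-normal(ln 6.0, 0.652) truncated at
the 1.8 threshold (location and scale matched to median 6.0, IQR 3.9–9.4);
negative-lesion SUVmax log-normal(ln 1.2, 0.30) truncated below threshold;
lesion site drawn independently as bone/node/lung/other with probabilities
0.40/0.30/0.10/0.20. PFS is exponential by default with all-positive median
21.6 months and the heterogeneous hazard multiplied by a true HR of
21.6/5.5 ≈ 3.93, so under the exponential family the hazard ratio equals
the median ratio and the truth is analytically known; a Weibull shape
option provides proportional-hazards stress tests. The cohort's *observed*
HR of 5.4 against a median ratio of 3.9 is a real-data feature the
generator deliberately does not target. Censoring is an independent
exponential time whose rate is solved numerically (class-mixture integral,
Brent bisection) to achieve the configured censoring fraction — 0.366 by
default (37/101 censored).

Each patient consumes a child stream spawned from the root seed
(`SeedSequence.spawn`), so cohorts are bitwise reproducible and unaffected
by loop reordering.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: correlation between SUV and lesion site or
between lesions within a patient; non-proportional hazards between groups
(beyond the Weibull option); informative censoring; inter-study calibration
differences in SUV; and the gap between the cohort's HR (5.4) and its
median ratio (3.9), which the exponential family cannot produce. Tests on
synthetic cohorts validate the *estimators* (bias, CI coverage in
[0.92, 0.98] at n = 200, median recovery within 5% at n = 5,000), not
clinical effect sizes.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to make their tolerances meaningful
while keeping the suite quick: meta-analytic parameter recovery at k = 200
studies × 100 replicates (μ within ±0.05, τ² within ±0.08); Cox log-HR bias
at n = 400 uncensored patients × 200 replicates (|bias| < 0.05); Wald
coverage at n = 200 × 500 replicates; Begg exact-vs-normal agreement over
1,000 simulated k = 8 meta-analyses. The published-table reproductions are
closed-form evaluations on the built-in evidence table and run in
milliseconds.

## Known limitations

* No meta-regression, subgroup moderators, or network meta-analysis; no
  Egger regression or trim-and-fill; no multivariable or time-varying Cox.
* SE reconstruction covers CIs only, not p-values or interquartile ranges.
* The ratio-of-medians SE treats arms as independent (distinct patient
  groups); no within-study correlation model.
* SUV values arrive precomputed; no image handling of any kind.
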