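# fesmeta

Evidence synthesis and individual-patient-data (IPD) survival analysis for
estrogen-receptor–targeted PET imaging of metastatic breast cancer (mBC).

[¹⁸F]FES PET measures, lesion by lesion, whether tumor tissue still carries
ligand-accessible estrogen receptor: a lesion is called FES-positive when its
SUVmax is at or above a positivity threshold (1.8 in the primary analysis),
and a patient whose disease mixes FES-positive and FES-negative lesions is
*FES-heterogeneous*. Heterogeneity of FES uptake predicts a poor response to
endocrine therapy, and this package implements the statistical machinery
needed to quantify that, both from published study summaries and from
lesion-level patient data:

* **Effect reconstruction** — turn published summaries into log-scale
  effects with standard errors: `SE = (ln hi − ln lo)/(2z)` from a Wald CI,
  symmetric log-scale imputation of unbounded upper limits, delta-method
  ratios of group medians, Hedges' g, and Haldane-corrected odds ratios.
* **Pooling engine** — fixed-effect (FEM) and random-effects (REM)
  inverse-variance pooling on the log scale with Cochran Q, I², and
  DerSimonian–Laird τ²: `θ̂ = Σwθ/Σw`, `w = 1/se²` (FEM) or `1/(se²+τ²)`
  (REM), `I² = max(0, (Q−df)/Q)·100`.
* **Bias diagnostics** — funnel-plot coordinates and the Begg–Mazumdar rank
  correlation between standardized deviates and variances, with an exact
  permutation p-value for small meta-analyses.
* **IPD survival** — SUVmax lesion/patient classification, Kaplan–Meier
  curves, a binary-covariate Cox model (Newton–Raphson on the Efron partial
  likelihood), and a positivity-threshold sweep over 1.8–4.0 in 0.1 steps.
* **Synthetic cohorts** — seeded generators reproducing the structure of the
  pooled 101-patient / 878-lesion FES cohort (median 7 lesions per patient,
  IQR 4–12; lesion SUVmax median 6.0; ~25% heterogeneous patients; group
  median PFS 21.6 vs 5.5 months), so the full pipeline is testable offline.

The five-study evidence table that drives the study-level analyses ships as
a built-in fixture (`fesmeta.table1_fixture()`).

## Worked example

Dump the built-in evidence table and pool the four published hazard ratios
(FES-heterogeneous vs all-FES-positive PFS):

```bash
fesmeta fixtures --out-dir fixtures
fesmeta pool fixtures/table1_hr.csv --out-dir pooled
```

prints (abridged):

```json
{
  "k": 4,
  "FEM": {"point": 4.575, "ci_low": 2.727, "ci_high": 7.675,
          "Q": 11.389, "p_Q": 0.0098, "i_squared": 73.66},
  "REM": {"point": 5.053, "ci_low": 1.820, "ci_high": 14.027,
          "tau2": 0.794}
}
```

So patients with FES-heterogeneous disease progress about 4.6 times faster
(fixed effect; 95% CI 2.7–7.7) than patients whose lesions are uniformly
FES-positive, with real between-study variability (Q = 11.4 on 3 df,
p = 0.010; I² = 74%); the random-effects sensitivity estimate is 5.1.

The same pipeline runs on lesion-level data. With a synthetic cohort:

```bash
fesmeta simulate --seed 1 --out-dir sim        # 101 patients, 878 lesions
fesmeta ipd sim/lesions.csv sim/survival.csv --threshold 1.8 --out-dir out
fesmeta sweep sim/lesions.csv sim/survival.csv --sweep 1.8:4.0:0.1 --out-dir out
```

the classification step reports 80 all-FES-positive and 21 not-all-positive
patients, group median PFS 17.0 vs 5.7 months, and a Cox hazard ratio of
3.32 (95% CI 1.91–5.79) for heterogeneous disease; `out/sweep.tsv` tabulates
how the contrast attenuates as the positivity threshold rises.

Library use mirrors the CLI:

```python
import fesmeta as fm

fx = fm.table1_fixture()
pooled = fm.fixed_effect_pool(list(fx.hazard_ratios))
print(pooled.point, pooled.ci_low, pooled.ci_high)   # 4.575 2.727 7.675
```

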