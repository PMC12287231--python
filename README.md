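# sirsurv

Prognostic evaluation of systemic-inflammation biomarkers — the
neutrophil-to-lymphocyte ratio (NLR), the platelet-to-lymphocyte ratio
(PLR) and their combination (CNP) — in right-censored survival cohorts,
with the hepatocellular-carcinoma (HCC) setting as the motivating use case.

## The problem

Cheap blood-count ratios are attractive prognostic biomarkers, but the
standard workflow for turning a continuous marker into a clinical rule is
statistically treacherous:

1. **Functional form.** Is the hazard log-linear in the marker, or in some
   transform of it?  `sirsurv` selects the form with **fractional
   polynomials** (powers {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, 0 ≡ log) and the
   Royston–Altman closed χ² deviance test.
2. **Optimal cutoff.** Dichotomising at the cutoff that *minimises the
   p-value* of the Cox hazard ratio is popular but anti-conservative: on
   pure-noise data it "finds" a significant cutoff far more than 5% of the
   time, and the hazard ratio attached to the winning cutoff is inflated.
3. **Shrinkage.** The package corrects that winner's curse with a
   **bootstrap-percentile calibration-slope shrinkage**: every bootstrap
   replicate re-runs the *entire* cutoff search, the replicate model is
   evaluated on the original cohort through a one-parameter Cox calibration
   fit, and the mean calibration slope multiplies the naive log-HR; the 95%
   CI comes from the percentiles of the slope × naive-log-HR distribution.
4. **Incremental value.** Does the biomarker add anything to a clinical
   Cox model (age, AFP > 400 ng/mL, Child–Pugh class, BCLC or ITA.LI.CA
   stage)?  Evaluated with **Harrell's C** and the **integrated
   discrimination improvement (IDI)** at a fixed horizon, with
   inverse-probability-of-censoring weights and a subject-level bootstrap.

The core survival machinery (Kaplan–Meier with Greenwood variance and
log(−log) bands, multi-group log-rank, Efron-tie Cox partial likelihood
with Newton–Raphson and Breslow baseline) is implemented on numpy arrays
and cross-checked against `lifelines` in the test suite; the cutoff scan is
vectorised over candidates so that bootstrap-within-scan procedures run in
seconds.

Because patient-level registry data of this kind are not public, the
package ships a first-class **synthetic cohort generator**
(`sirsurv.simulate`): log-normal NLR/PLR marginals calibrated to published
cohort summaries (median NLR 2.22, IQR 1.63–3.18; median PLR 87, IQR
58–124), a Gaussian copula hitting Spearman ρ = 0.56, Table-1-style
clinical covariate frequencies, and Weibull-baseline Cox survival times
(months) with a logarithmic NLR effect and a linear PLR effect, under
continuous / threshold / null effect modes.

## Worked example

```python
import sirsurv as ss

cfg = ss.SimulationConfig(seed=123, n_subjects=1000)
cohort = ss.add_biomarkers(ss.simulate_cohort(cfg))

scan = ss.minp_cutpoint(cohort["nlr"], cohort["os_time"], cohort["os_event"])
print(f"cutoff {scan.selected_cutoff:.3f}  HR {scan.selected_hr:.2f}  "
      f"p {scan.selected_p:.2e}")

shr = ss.bootstrap_shrinkage(cohort["nlr"].to_numpy(),
                             cohort["os_time"].to_numpy(),
                             cohort["os_event"].to_numpy(),
                             n_bootstrap=200, seed=1)
import numpy as np
print(f"naive HR {np.exp(shr.naive_log_hr):.2f}  "
      f"shrunken HR {np.exp(shr.shrunken_log_hr):.2f}  "
      f"factor {shr.shrinkage_factor:.2f}")
```

prints

```
cutoff 2.107  HR 1.61  p 5.88e-09
naive HR 1.61  shrunken HR 1.51  factor 0.87
```

— the scan picks the cutoff with the smallest Wald p-value over the
candidate grid, and the bootstrap attenuates the selection-inflated hazard
ratio (here by a calibration slope of 0.87; on pure-noise cohorts the
attenuation is far stronger) exactly as the method is designed to do.

The full pipeline — functional form, cutoffs, shrinkage, CNP Kaplan–Meier
curves, and the clinical vs clinical+biomarker model comparison with
C-index and IDI — runs from the command line:

```bash
sirsurv simulate --seed 123 --n 1043 --out cohort.csv
sirsurv validate cohort.csv
sirsurv analyze-os --cohort cohort.csv --seed 1 --out-dir results/os
sirsurv analyze-rfs --cohort cohort.csv --seed 1 --out-dir results/rfs \
    --cutoff-nlr 1.45 --cutoff-plr 188
```

All tabular outputs are TSV, curve data reproduce at-risk tables, and a
JSON manifest records configuration, seeds and per-stage record counts.
Recurrence-free survival reuses the OS cutoffs and excludes recurrences
within the first 3 months (curative treatments LT/LR/ABL only).

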