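# Methods

This note documents the statistical model behind `sirsurv`, the design
choices that were genuinely open, and what the synthetic-data tests do and
do not establish.

## Survival engine

Cox proportional-hazards models are fitted by maximising the exact partial
likelihood with Newton–Raphson and step-halving; convergence is declared
when the largest coefficient update falls below 1e-8 (max 100 iterations),
which leaves the score below 1e-6 in every component.  Tied event times use
the Efron correction by default — observational registries record time in
months, so ties are heavy in real data and in bootstrap resamples — with
Breslow available by flag.  A monotone partial likelihood (perfect
separation) is detected either by a coefficient excursion beyond |β| = 40
or by the information matrix flattening along the diverging direction; the
fit is returned flagged non-converged rather than raising, while a singular
information matrix at the start (collinear design) is an error.  The
baseline cumulative hazard is the Breslow estimator at covariates 0, so
fixed-horizon risks are `1 − exp(−H0(t)·exp(xβ))`.

The implementation is vectorised over numpy arrays.  Risk-set sums are
computed as segment sums between consecutive risk-set boundaries followed
by a reverse cumulative sum over event groups, with the (k × k) Hessian
blocks kept flattened; the no-tie/Breslow level of the Efron sum telescopes
into a single weighted segment product.  A dedicated scan fitter estimates
all single-indicator (biomarker > c) models of a cutoff grid simultaneously
(for binary covariates x² = x, so the Efron sums collapse to scalars per
group-candidate pair).  This is what makes bootstrap-within-scan procedures
(≈ 2×10⁴–10⁵ univariate fits per analysis) run in seconds.  `lifelines`
is the independent cross-check in the test suite (coefficients, standard
errors and log-likelihood agree to ~1e-6 on tie-heavy data) and supplies
the multi-group log-rank test; Kaplan–Meier curves carry Greenwood
standard errors, log(−log)-transformed confidence bands, and a median CI
read off the band crossings of 0.5.

Harrell's C counts pairs where an event subject has a strictly shorter
time than the other subject's observed time; tied risks count one half.
Times are months throughout.

## Functional-form selection

Fractional polynomials over the canonical power set
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ log; FP2 pairs use the
repeated-power rule x^p, x^p·log x).  The biomarker is pre-scaled by its
geometric mean, which makes the selected power set invariant to positive
rescaling.  Selection uses the closed testing procedure at α = 0.05:
best-FP2 vs null (4 df), vs linear (3 df), vs best-FP1 (2 df), each as a
χ² deviance difference.  The search can be adjusted for the clinical
covariates and the pipeline adjusts by default, mirroring a
multivariable-FP analysis of a single continuous predictor; the univariate
search remains available.  Non-convergent candidate transforms are dropped
with a warning.

A practical caveat established by the simulation tests: with a
logarithmic effect of the size published for NLR (HR 1.61 per unit log-NLR,
marginal log-SD ≈ 0.50), log(x) and its neighbouring powers x^±0.5
correlate above 0.99 over the observed range, so the *best* FP1 power is
log in only a modest majority of replicates at n = 2,000 — adjacent powers
absorb much of the remainder.  Form identification at this effect size is
intrinsically noisy; the closed test's *null vs any-effect* decision is, by
contrast, essentially always correct.

## Minimum-p cutoff selection

Candidates are the unique observed values between the 10th and 90th
percentiles (both configurable; a permissive 5% lower bound suits markers
whose published cutoff sits deep in the lower tail), thinned to at most
100 evenly spaced unique values, and constrained to leave at least a
configurable fraction of subjects (default 2%) and one event on each side.
The scan statistic is the Wald p of the univariate Cox HR on the strict
indicator (biomarker > c); values equal to the cutoff stay in the lower
group.  A log-rank (score-test) statistic is available for cross-checking.
Ties in the minimum are broken toward the smallest cutoff.  The full scan
(cutoff, HR, CI, p) is retained and exportable for effect-curve plots, and
every grid decision is recorded in the result for auditability.  No
multiplicity correction is applied to the selected p-value — the package
corrects the *effect estimate* instead, by shrinkage.

## Bootstrap shrinkage

The calibration-slope (Van Houwelingen-style) variant with mandatory
within-replicate re-selection is the default: resample subjects with
replacement; re-run the entire cutoff search in the replicate; fit the
(optionally covariate-adjusted) Cox model there; evaluate that model's
linear predictor on the original cohort; fit a one-parameter Cox of the
original outcomes on it.  The mean slope over replicates is the shrinkage
factor, the shrunken log-HR is factor × naive log-HR, and the 95% CI is
the 2.5/97.5 percentile of slope × naive log-HR; the p-value is the
two-sided percentile position of that distribution around zero (with a
+1 continuity correction).  A bias-subtraction variant
(naive − (mean replicate estimate − naive)) sits behind a flag.
Replicates with degenerate dichotomisations or failed fits are dropped and
counted; more than 10% failures raises a warning.  Defaults: 1,000
replicates (hard floor 200), subject-level resampling without
stratification.

On null cohorts (n = 500) the simulations show the naive selected-cutoff
test rejecting at α = 0.05 in roughly 45% of datasets, mean |log-HR|
roughly halved by shrinkage, and a mean calibration slope near 0.54 —
against ≈ 1.19 when re-selection inside replicates is (wrongly) disabled.
That ordering is asserted by the suite: the optimism is created by the
selection step, and only honest re-selection sees it.

## Discrimination and IDI

The clinical model carries age (years), AFP > 400 ng/mL, Child–Pugh class
dummies (reference A) and staging dummies (reference stage 0), with BCLC
or ITA.LI.CA staging selectable; empty levels drop their dummy with a
warning.  Extended models add either log(NLR) + PLR/100 (continuous
block) or CNP dummies against CNP = 0.  PLR enters per 100 units — the
published per-unit scale of its linear HR is ambiguous, so the scale is a
parameter and per-100 the package default.

IDI at horizon t is the between-model change of the discrimination slope
D = E[risk | event by t] − E[risk | event-free at t], with predicted risks
from the Breslow baseline and IPCW weights from a Kaplan–Meier fit of the
censoring distribution (events by t weight 1/G(t⁻), survivors 1/G(t),
weights capped at 20 with a warning; the censored-before-t contribute only
via the weights).  With no censoring the weights are identically 1 and the
estimator reduces to the plain Pencina difference — asserted exactly in
the suite.  The horizon is never implied by the method itself; the package
default is 36 months, near the emulated cohort's ~40-month median
follow-up, and it is always printed in reports.  Inference is a
subject-level bootstrap (default 500 replicates, 200 in the heavier test
scenarios) that refits both models per replicate; C-index CIs come from
the same replicates.  Interactions between biomarkers and covariates are
supported as optional product terms, off by default.

## Synthetic cohort generator

The generator emulates the statistical structure of a Western HCC registry
cohort; its defaults are the study conditions of the test suite.

* **Biomarker marginals.** Log-normal, pinned by two published quantile
  facts each: NLR median 2.22 and IQR (1.63, 3.18) give μ = log 2.22,
  σ = log(3.18/1.63)/(2·0.6745) ≈ 0.495; PLR median 87 and IQR (58, 124)
  give σ ≈ 0.563; lymphocytes median 1.31, IQR (1.0, 1.8) (10³ cells/mm³).
  Neutrophil and platelet counts are back-computed as ratio × lymphocytes,
  so panels recompute exactly.
* **Dependence.** Gaussian copula with ρ_Pearson = 2·sin(π·ρ_Spearman/6),
  targeting ρ_S = 0.56.  Realised Spearman ρ is strictly increasing in the
  target (asserted).  In real data part of the NLR–PLR correlation flows
  through the shared lymphocyte denominator; here it is carried entirely
  by the copula, with lymphocytes independent.
* **Covariates.** Child–Pugh (70/27/3%), BCLC (15/42/15/24/4%), ITA.LI.CA
  (22/41/22/15%) — the two staging systems are coupled comonotonically
  through a shared uniform — treatment mix (LT 3, LR 19, ABL 33, IAT 31,
  SOR 8, BSC 6%), age ~ N(68, 11²) clipped to [18, 95].  AFP > 400
  prevalence is not derivable from published medians; it is fixed at 0.12,
  a plausible share for a Western cohort dominated by early-stage disease.
* **Effects.** Continuous mode: log-HR log(1.61) per unit log NLR and
  log(1.16) per 100 PLR units; covariate log-HRs follow the published
  adjusted clinical model (age 1.01/yr, AFP 1.38, Child–Pugh B 1.50,
  C 0.97, BCLC A–D 1.66/2.77/4.36/11.0).  The Child–Pugh C value below 1
  is a sparse-level artifact of the source estimates, kept deliberately so
  synthetic cohorts reproduce that instability.  Threshold mode replaces
  the continuous terms with step effects at configurable true cutoffs;
  null mode zeroes the biomarker terms while keeping the covariate
  structure.
* **Outcomes.** Weibull-baseline Cox times in months (shape 1.1, scale 390
  — calibrated once so a typical covariate profile has median OS near the
  emulated cohort's ≈ 40 months); censoring is the minimum of an
  administrative cap (206 months, the longest published follow-up) and an
  exponential time whose rate is solved by Brent's method to hit the
  target censored fraction (default 0.35; the realised fraction is within
  ±5 points at n = 5,000).  Recurrence times (curative treatments only)
  are Weibull (shape 0.8, scale 45) with *no* biomarker effect, matching
  the emulated study's null recurrence finding, censored at death.

What the generator does **not** emulate: competing risks (death from liver
failure vs cancer), biomarker–covariate dependence (published data show
NLR rising with Child–Pugh and both ratios with stage), multi-centre
heterogeneity, time-varying biomarkers, and treatment allocation driven by
stage.  Passing tests therefore demonstrate the *statistical machinery* —
selection bias, its correction, discrimination gains of a real effect —
not clinical transportability of any particular cutoff.

## Pipeline conventions

Cutoffs, functional forms and the CNP definition are frozen on the cohort
they were selected in and applied unchanged downstream (the RFS analysis
reuses OS cutoffs and never re-selects).  Early recurrences (< 3 months
after curative treatment) are excluded from the RFS set, with the count
recorded in the manifest; a landmark-censoring variant sits behind a flag.
Rows failing schema validation are excluded and counted, never coerced.
Runs are reproducible byte for byte under a fixed seed (the manifest's
timestamp aside); every stage writes its record counts to the JSON
manifest, and the suite asserts count conservation.

## Problem sizes in the test suite

Exact oracles run on ≤ 10-subject fixtures.  Simulation-based checks use
the sizes they were designed at: parameter recovery 50 × n = 2,000;
functional-form recovery 2 × 50 × n = 2,000; cutoff recovery
100 × n = 1,000; null-calibration 200 × n = 500 with shrinkage evaluated
on 60 of those cohorts (ablation on 30) at 200 bootstrap replicates; IDI
power 50 × n = 1,000 at 200 bootstrap replicates; generator calibration
n = 10,000; end-to-end determinism 2 × n = 1,043 at 200 replicates.  These
sizes keep the full suite near 15 minutes on one CPU while leaving every
Monte-Carlo margin wide relative to its threshold.
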