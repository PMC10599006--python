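# Methods

## Problem and model

After out-of-hospital cardiac arrest, hypoxic–ischaemic brain injury
produces cytotoxic oedema, which restricts water diffusion and lowers the
apparent diffusion coefficient (ADC, in 10⁻⁶ mm²/s) on diffusion-weighted
MRI. `neuroadc` implements a voxel-based quantitative analysis of
ultra-early ADC maps for predicting poor neurological outcome (Cerebral
Performance Category 3–5 at six months, versus good, CPC 1–2), together
with the comparison predictors used in that setting: the CT grey/white
matter ratio (GWR), the pupillary light reflex (PLR) and serum
neuron-specific enolase (NSE).

Two imaging predictors are computed per patient from the parenchymal ADC
voxels:

* **mean whole-brain ADC** — the arithmetic mean of retained parenchymal
  values;
* **ADC-PercentValue(t)** — for each threshold t on the grid
  250, 300, …, 1150:

  PV(t) = 100 · |{v : 200 ≤ v ≤ t}| / |{v : 200 ≤ v ≤ 2000}|

Voxels above 2000 ×10⁻⁶ mm²/s (CSF, artefact, noise) are excluded before
any metric is computed. Metrics are voxel-count ratios: voxels are not
volume-weighted and anisotropic voxels are not resampled.

Prognostic performance is scored by ROC analysis oriented so that the
positive class is poor outcome. The operating point is the **FPR-0
cutoff**: among all thresholds with zero false positives on the data, the
one maximising sensitivity. AUCs carry DeLong placement-value standard
errors, normal-approximation CIs truncated to [0, 1], and are compared
between correlated predictors with the paired DeLong z-test. Sensitivity,
specificity, PPV and NPV are reported as percentages with exact two-sided
95% Clopper–Pearson intervals. Combined models are logistic regressions
(poor outcome on PLR absence, NSE, and one imaging metric) after a
univariable screen at P < 0.1 and backward elimination at P ≥ 0.05; the
fitted linear predictor is itself scored by ROC.

## Numerical and convention choices

* **"Below threshold" boundary.** The PV numerator uses `v ≤ t`
  (inclusive), matching the closed summation limits of the defining
  ratio; a strict `v < t` dialect is available via `boundary="lt"` and is
  recorded in all output metadata.
* **Sweep grid.** Thresholds step by 50 from 200 to 1200, but the
  reported grid is 250–1150: PV(200) counts only exact-200 voxels and is
  degenerate, and PV at 1200 is not defined under the 200–2000 window.
  Both endpoints are echoed in the provenance JSON.
* **Mean whole-brain window.** By default the mean is computed over the
  same closed [200, 2000] window as the PV denominator, since the
  exclusions are defined once for the whole analysis; whether values
  below 200 should be included is genuinely open, so
  `include_below_window=True` switches to a [0, 2000] window.
* **Cutoff placement.** The internal FPR-0 threshold is the largest
  good-outcome score; the reported cutoff is the midpoint between it and
  the next distinct observed value, with the orientation symbol (`>` for
  higher-is-poor predictors such as PV, `<` for lower-is-poor ones such
  as mean ADC and GWR). When no observed value exceeds the good-group
  maximum the result is flagged degenerate (sensitivity 0), not an error.
* **Ties.** AUC ties count ½ (Mann–Whitney convention). Backward
  elimination breaks p-value ties by column order, so selection is
  deterministic.
* **Separation.** Perfect or quasi-separation in a logistic fit (slope
  |β| > 50 or non-finite SE) is flagged rather than reported as a
  spurious p-value; the intercept is exempt because covariates far from
  zero (ADC in raw units) legitimately give large intercepts.
* **Elimination threshold.** Entry is screened at P < 0.1; the backward
  removal threshold is 0.05 (a common statistics-package default),
  recorded in the model report.
* **Multiple testing.** No correction is applied across the 19-threshold
  sweep; each threshold's ROC row is descriptive. Callers comparing many
  thresholds should treat the per-row p-values accordingly.

## The synthetic cohort generator

No patient-level data are available, so every downstream stage is
exercised on a synthetic cohort whose group-level statistics emulate the
clinical setting. Each patient is an ellipsoidal three-compartment phantom
(48×48×36 voxels at 3.6×3.6×4.0 mm by default — a deliberately coarse
grid that keeps a 131-patient cohort fast while leaving ~25,000
parenchymal voxels per patient):

* **parenchyma** at a group mean of 790 (good) / 785 (poor) ×10⁻⁶ mm²/s;
* **CSF** in two ventricle-like interior ellipsoids at 2600, so CSF
  self-excludes under the >2000 rule even without its mask label;
* a single **contiguous lesion** — the fraction f of parenchymal voxels
  nearest a random seed voxel — at 450, with f ~ Beta(1, 60) in the good
  group (concentrated near 0) and Beta(2, 10) in the poor group;
* additive Gaussian voxel noise (σ = 90), truncated at zero.

The mixture mean (1−f)·parenchyma + f·lesion then gives expected group
medians of mean whole-brain ADC near 786 (good) and 736 (poor), inside
the published interquartile bands the generator is calibrated against
(771.9–799.6 and 673.2–775.1). Covariates are drawn conditionally on
outcome: PLR presence Bernoulli(0.88 / 0.38); NSE log-normal with
log-medians log 23.8 / log 44.0 ng/ml and a common log-sd of 0.5; CT ROI
attenuations Gaussian around means chosen so the GWR medians are ≈1.27 /
≈1.21. Outcomes themselves are Bernoulli with poor-outcome prevalence
74/131.

What the phantom does **not** emulate: real neuroanatomy, partial-volume
effects, registration error, scanner artefacts, regional lesion
predilection, and — importantly — within-group correlation between
predictors (covariates are conditionally independent given outcome) and
realistic between-patient overlap. The phantom's groups separate more
cleanly than real patients do (mean-ADC AUC ≈0.99 on the synthetic cohort
versus ≈0.8 in clinical practice), so passing recovery tests demonstrates
that the machinery is correct and calibrated, not that real-data
performance would match.

## Validation strategy

Quantities that depend on the original patient-level data (the clinical
AUCs, cutoff values such as 739.2 ×10⁻⁶ mm²/s, odds ratios) cannot be
reproduced; the machinery behind them is validated structurally instead:

* AUC against an O(n²) pairwise-concordance oracle on 1,000 random
  instances (with and without heavy ties), to machine precision;
* the FPR-0 cutoff against an exhaustive scan over every threshold
  position on 1,000 random instances;
* the paired DeLong test against a 2,000-replicate outcome-stratified
  bootstrap of the AUC difference on a 20-seed grid of paired scores
  (n = 500; half null designs, half with a genuine AUC gap). The
  bootstrap decision rule is a z-test with the bootstrap SE — the same
  statistic and reference law as the analytic test with a
  resampling-based variance — because a percentile-CI rule disagrees by
  construction on null draws whose p-value lands within sampling error of
  the 0.05 boundary;
* Clopper–Pearson intervals against explicit binomial-tail inversion, and
  their coverage on an (n ∈ {10, 50, 100}) × (p ∈ {0.1, 0.5, 0.9}) grid:
  the analytic coverage (pmf sum) is verified ≥ 95% in every cell, and a
  2,000-replicate empirical simulation is checked against the analytic
  value to Monte-Carlo error (the empirical estimate alone can dip a few
  tenths of a percent below 95% by noise even though exact intervals are
  provably conservative);
* calibration recovery on a 200-patient default cohort: group medians of
  mean whole-brain ADC inside the published IQR bands, per-patient
  monotone threshold sweeps, and a combined PLR+NSE+ADC model at least as
  discriminative as its best single predictor.

Problem sizes (32×32×24 recovery volumes, 1,000 oracle instances, 20
bootstrap seeds, 2,000 replicates) were chosen to make the full
validation run in seconds to minutes on one CPU while keeping Monte-Carlo
error well below the margins being asserted.

## Known limitations

* The rule-based fallback masker (largest connected component in a
  plausible intensity range plus morphological closing) is a simple
  stand-in for semi-automatic skull-stripping and is only expected to
  work on phantom-like volumes; real acquisitions should ship a mask.
* Whether bilateral CT ROIs are averaged is left to the caller
  (`average_bilateral`); slice selection is operator-dependent and not
  modelled.
* The DeLong AUC CI is a normal approximation; near AUC = 1 it is
  truncated rather than transformed.
* Backward elimination explores a single deletion path; it does not
  guarantee the globally best subset.
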