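# Methods

This document records the statistical model, the numerical conventions, the
synthetic-cohort generator's scope, and the design decisions that fill gaps
where the published summaries do not fully determine an implementation.

## The risk system

Each patient is dichotomized on four suspicious features of the primary
lesion:

| Rule name | Feature | Suspicious when |
| --- | --- | --- |
| `birads5` | BI-RADS category | equal to 5 |
| `tumor_emin_low` | tumor E_min | ≤ 3.31 kPa (inclusive) |
| `shell3_emin_low` | 3 mm-shell E_min | ≤ 3.52 kPa (inclusive) |
| `stiff_rim_present` | stiff-rim sign | present |

Low minimum stiffness is the suspicious direction for the quantitative SWE
features: metastasis-prone lesions show necrotic or infiltrative soft cores,
so small E_min values discriminate positives. Rules are data (a tab-separated
file loadable by `DichotomizationRuleSet`), not code.

Three scores are built from the resulting 0/1 flags:

- **Regression**: linear predictor of a multivariate logistic model of LN
  status on the four flags (intercept included).
- **Weighting**: integer-weighted sum with weights = fitted odds ratios
  rounded half-up and floored at 1. All four published ORs (2.155, 1.654,
  1.564, 1.900) round to 2, so the published weighting score is exactly twice
  the counting score.
- **Counting**: number of suspicious features present among those with fitted
  OR > 1 — the 0–4 **risk grade**.

Evaluation per score: tie-corrected rank AUC with a DeLong confidence
interval, the Youden-index cutoff over observed score values, sensitivity
and specificity there with exact Clopper–Pearson intervals, and pairwise
DeLong tests between the correlated AUCs.

Grade-wise analysis tabulates LN status by grade, reports within-grade
positivity, unadjusted 2×2 odds ratios of each grade against a chosen
(possibly pooled) reference grade set with Wald intervals, and the
Cochran–Armitage trend test across grades.

## Statistical conventions

All primitives live in `axrisk.stats` and are implemented from first
principles; scipy is used only for distribution functions and `rankdata`.

- **Mann–Whitney U**: mid-ranks for ties; tie-corrected normal approximation
  (continuity correction optional, off by default); exact enumeration when
  both groups have ≤ 8 observations and no ties.
- **Rank AUC**: (wins + ½ ties) / (n₁·n₀) via mid-ranks; identical to the
  trapezoidal area under the empirical ROC curve (tested to 1e-12).
- **ROC curves**: thresholds are the observed values plus a sentinel extreme;
  `direction` is explicit (`suspicious_if_low` / `suspicious_if_high`) —
  quantitative SWE screening uses *low*, risk scores use *high*. Cutoff
  comparisons are inclusive (≤ for low, ≥ for high).
- **Youden cutoff**: maximizes sens + spec − 1; ties broken toward higher
  sensitivity, then the less extreme threshold.
- **Proportion CIs**: Clopper–Pearson exact, from beta quantiles; the
  degenerate ends use 0 and 1 exactly.
- **2×2 odds ratios**: cross-product with Wald CI on the log scale
  (z = Φ⁻¹(0.975) ≈ 1.959964); Haldane–Anscombe +0.5 added to *all* cells
  when any cell is zero.
- **Logistic regression**: IRLS to tolerance 1e-10 (max 100 iterations),
  Wald standard errors from the inverse Fisher information; complete or
  quasi-separation is reported (`separation=True`, `converged=False`) when
  coefficients diverge during or after fitting (|β| > 20).
- **DeLong**: placement-value variance for single-curve CIs and the paired
  test of two correlated AUCs; the reported p-values are two-sided normal.
- **Cochran–Armitage**: default scores 0..G; the variance uses the pooled
  positivity, so for two grades z² equals the Pearson chi-square exactly.

Rounding of reported headline values follows round-half-away-from-zero at
the stated printed precision.

## Contingency fixtures

`axrisk.fixtures` packages the published contingency tables: the 5×2
grade-by-LN table (negatives 39/126/142/116/22, positives 3/30/46/64/31; 619
patients, 174 LN-positive), the stiff-rim 2×2 table, BI-RADS / T-stage /
location by LN status, and the per-group median/IQR summaries of all 17
quantitative features with the two published E_min cutoffs. Expanding a
contingency table into per-subject (grade, outcome) pairs makes every
rank-based statistic computable exactly from printed counts —
`pipeline.reproduce_printed` verifies 46 such values at printed precision.

## Synthetic cohort generator

Raw per-patient data are not available, so `axrisk.synthetic` draws cohorts
calibrated to the published group-wise summaries:

- LN status is Bernoulli with prevalence 174/619 by default.
- BI-RADS and the stiff-rim sign are drawn per LN group from the published
  frequencies.
- Each of the 16 region SWE statistics is log-normal per LN group with
  μ = ln(median) and σ = ln(q3/q1) / (2·z₀.₇₅) from the published median and
  quartiles. This closed form reproduces the median and the quartile *ratio*
  exactly; for log-asymmetric IQRs the individual quartiles cannot both be
  matched by any log-normal.
- Within a patient the 16 statistics share a one-factor Gaussian copula
  (Z = √ρ·f + √(1−ρ)·ε, ρ = 0.7 by default); E_ratio is drawn
  independently.
- Records violating e_min ≤ e_mean ≤ e_max in any region are redrawn
  (up to 1000 attempts, then the three values are sorted). This truncation
  biases E_min medians downward by up to ~10% (strongest in the shells);
  the spec-level calibration — the tumor E_min operating point at the 3.31
  cutoff within ±0.05 of the published 59.77%/55.96% — is unaffected.
  Calibration checks via `validate_against_summaries` should use a tolerance
  of ~0.15 for E_min medians.
- Age, tumor size, T stage and location are drawn group-independently from
  the published whole-cohort margins; they carry no signal by construction
  and exist to exercise the full data model.
- All randomness flows from one `numpy` `default_rng(seed)` in a fixed,
  documented draw order, so a configuration determines the cohort
  byte-for-byte.

**Scope and limits.** The generator matches group-wise marginals and a
plausible within-patient correlation; it does *not* model the joint
dependence between BI-RADS, the stiff-rim sign and the SWE features beyond
their shared LN-group conditioning. Consequently multivariate quantities
(adjusted ORs, the counting-grade AUC on synthetic data) approximate but do
not reproduce the published ones — on large synthetic cohorts the counting
AUC lands in roughly 0.60–0.70 versus the published 0.656.

## Design decisions

Choices the published summaries leave open, as implemented:

- The stiff-rim sign is treated as suspicious when **present**, matching the
  running text and the fitted OR direction.
- OR-to-weight conversion is round-half-up with a floor of 1.
- The counting grade includes only features whose fitted OR exceeds 1.
- Youden ties break toward sensitivity; cutoffs are inclusive.
- Zero cells get the Haldane–Anscombe correction rather than infinite ORs.
- Reference grades for OR tables may be pooled (e.g. grades 0–1), with the
  reference row carrying OR exactly 1 and no interval.
- CSV round-trips are bit-exact: writes use `%.17g`, reads use
  round-trip float parsing; invalid rows are dropped with per-row
  diagnostics rather than failing the whole file, while missing required
  columns are a hard error.
- Every convention in effect is echoed into the pipeline's `run_log.json`.

## Limitations

- Fixture-derived statistics are exact; anything requiring raw per-patient
  feature values (Tables of medians, univariate ROC on real data) is only
  approximated through the synthetic generator.
- The logistic model reports Wald inference; no profile-likelihood or exact
  intervals.
- The DeLong single-curve interval is normal-theory and can be anti-
  conservative for AUCs near 1 with few positives.
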