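# axrisk

Axillary lymph-node (LN) metastasis risk grading for invasive breast cancer
from shear-wave elastography (SWE) and BI-RADS features.

Preoperative prediction of axillary LN metastasis guides whether a patient
needs sentinel lymph node biopsy. This package implements a comprehensive
risk system built on four dichotomized suspicious features of the primary
breast lesion:

1. **BI-RADS category 5** on conventional ultrasound;
2. **tumor E_min ≤ 3.31 kPa** — minimum elastic modulus inside the lesion;
3. **3 mm-shell E_min ≤ 3.52 kPa** — minimum modulus of the peritumoral
   3 mm shell;
4. **stiff-rim sign present** — qualitatively increased peritumoral
   stiffness.

Counting the suspicious features present gives each patient a **0–4 risk
grade**. Two alternative scores are built from the same flags — the logistic
regression linear predictor and an integer odds-ratio-weighted sum — and all
three are compared head-to-head with paired DeLong tests. When the integer
weights coincide (as they do with the published odds ratios, which all round
to 2), the weighting and counting scores are order-isomorphic and share every
rank-based diagnostic metric.

The statistical primitives (Mann–Whitney U, chi-square, rank/trapezoid AUC,
ROC with Youden cutoffs, Clopper–Pearson intervals, 2×2 odds ratios, IRLS
logistic regression with Wald inference, DeLong tests, Cochran–Armitage
trend) are implemented from first principles in `axrisk.stats` and verified
against independent oracles in the test suite.

## Worked example

A lesion with BI-RADS 4C, stiff rim present, tumor E_min 3.60 kPa and
3 mm-shell E_min 0.84 kPa trips two of the four rules (shell E_min and stiff
rim; 3.60 kPa is above the 3.31 tumor cutoff and 4C is not category 5), so it
receives risk grade 2.

The packaged grade-by-LN contingency fixture reproduces every published
headline number exactly:

```python
from axrisk import fixtures
from axrisk.cohort import expand_contingency
from axrisk.grades import grade_ors
from axrisk.stats import auc_rank, roc_points, youden_cutoff

gc = fixtures.GRADE_CONTINGENCY
grades, outcome = expand_contingency(gc)           # 619 subjects
auc = auc_rank(grades, outcome)
curve = roc_points(grades.astype(float), outcome, direction="suspicious_if_high")
cutoff, sens, spec = youden_cutoff(curve)
print(f"AUC {auc:.3f}; cutoff grade >= {cutoff:g}: "
      f"sens {100*sens:.2f}%, spec {100*spec:.2f}%")
print(grade_ors(gc, reference=(0,)).round(3).to_string(index=False))
```

prints

```
AUC 0.656; cutoff grade >= 3: sens 54.60%, spec 68.99%
grade  negative  positive  odds_ratio  ci_low  ci_high  p_value  reference
    0        39         3       1.000     NaN      NaN      NaN       True
    1       126        30       3.095   0.896   10.696    0.074      False
    2       142        46       4.211   1.243   14.271    0.021      False
    3       116        64       7.172   2.132   24.132    0.001      False
    4        22        31      18.318   5.016   66.892    0.000      False
```

## What's in the box

| Module | Purpose |
| --- | --- |
| `axrisk.stats` | From-scratch statistical primitives with documented conventions |
| `axrisk.cohort` | Validated per-patient data model and CSV round-tripping |
| `axrisk.fixtures` | Published contingency tables and summary statistics |
| `axrisk.synthetic` | Seeded synthetic-cohort generator calibrated to the published summaries |
| `axrisk.screening` | Univariate group comparisons and per-feature ROC analysis |
| `axrisk.risk` | Dichotomization rules, the four-feature logistic model, the three scores |
| `axrisk.grades` | Grade-wise contingency analysis: positivity, odds ratios, trend test |
| `axrisk.pipeline` | End-to-end pipeline and the published-value verification harness |
| `axrisk.cli` | Thin command-line interface (`axrisk simulate / analyze / reproduce / rules`) |

Narrative walk-throughs live in `examples/`; methodological details and
design decisions in `docs/methods.md`.

## Command line

```bash
axrisk simulate -n 10000 --seed 1 -o cohort.csv   # synthetic cohort CSV
axrisk analyze --input cohort.csv -o report/       # full analysis report
axrisk analyze -n 20000 --seed 3 -o report/        # same, on a fresh synthetic cohort
axrisk reproduce                                   # verify published headline values
axrisk rules                                       # print the default rule file
```

`analyze` writes CSV analogs of every results table (screening comparisons,
per-feature ROC, the final logistic model, the three-method comparison with
DeLong tests, grade contingency and odds-ratio tables), a markdown summary,
and a JSON run log recording every numerical convention in effect. Identical
configurations (including the seed) produce byte-identical reports.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers the statistics primitives against scipy / statsmodels /
scikit-learn oracles and closed forms, exhaustive-enumeration cross-checks,
property-based invariants (hypothesis, derandomized), generator calibration,
pipeline determinism, CLI behavior, and one test per acceptance criterion
(`tests/test_acceptance.py`).
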