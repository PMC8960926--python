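"""Univariate screening: which features separate LN-positive from LN-negative?

Reproduces the screening stage on a synthetic cohort: median/IQR group
comparisons with Mann-Whitney tests for the 17 quantitative SWE features,
chi-square tests for the categoricals, and per-feature ROC analysis with
Youden-index cutoffs (low stiffness is the suspicious direction).
"""

from axrisk.screening import compare_categorical, compare_continuous, feature_roc_table
from axrisk.synthetic import default_config, generate_cohort

cohort = generate_cohort(default_config(n=20_000, seed=7))

# 1. Quantitative features: group medians and Mann-Whitney p-values.
continuous = compare_continuous(cohort)
print("== continuous features (top 5 by p-value) ==")
print(continuous.nsmallest(5, "p_value").to_string(index=False))

# 2. Categorical features: within-level column percentages and chi-square.
print("\n== categorical features ==")
for feature, comp in compare_categorical(cohort).items():
    if comp.skipped:
        print(f"{feature}: skipped ({comp.note})")
        continue
    print(f"{feature}: chi2 p = {comp.p_value:.3g}")
    print(comp.table.to_string())

# 3. ROC analysis of each quantitative feature (suspicious if low).
roc = feature_roc_table(cohort)
print("\n== per-feature ROC (best 5 AUCs) ==")
cols = ["feature", "auc", "auc_low", "auc_high", "cutoff", "sens", "spec"]
print(roc.nlargest(5, "auc")[cols].to_string(index=False))
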