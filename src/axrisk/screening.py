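"""Univariate screening of clinical and SWE features between LN groups.

Three products, mirroring the usual structure of a diagnostic-accuracy study:
group-wise median/IQR with Mann-Whitney p per quantitative feature; category
counts with chi-square p per categorical feature; and a per-feature ROC table
(Youden cutoff with the "suspicious if low" convention, sensitivity and
specificity with exact binomial CIs, AUC with DeLong CI and a test of
AUC != 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    BIRADS_LEVELS,
    LOCATION_LEVELS,
    QUANT_COLUMNS,
    STIFF_RIM_LEVELS,
    T_STAGE_LEVELS,
    CohortTable,
)
from .stats import (
    chi2_independence,
    clopper_pearson_ci,
    delong_auc_ci,
    mann_whitney_u,
    roc_points,
    youden_cutoff,
)

__all__ = ["compare_continuous", "compare_categorical", "feature_roc_table"]

_CATEGORICALS = {
    "t_stage": T_STAGE_LEVELS,
    "location": LOCATION_LEVELS,
    "birads": BIRADS_LEVELS,
    "stiff_rim": STIFF_RIM_LEVELS,
}


def _split_groups(cohort: CohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    frame = cohort.frame
    neg = frame[frame["ln_status"] == "negative"]
    pos = frame[frame["ln_status"] == "positive"]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both LN groups must be present")
    return neg, pos


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # interpolation-free order statistics: quartiles are observed values
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="closest_observation")
    return float(med), float(q1), float(q3)


def compare_continuous(cohort: CohortTable) -> pd.DataFrame:
    """Per-feature group medians/IQRs and Mann-Whitney two-sided p-values."""
    neg, pos = _split_groups(cohort)
    rows = []
    for col in QUANT_COLUMNS:
        a = neg[col].to_numpy(dtype=float)
        b = pos[col].to_numpy(dtype=float)
        med_n, q1_n, q3_n = _quartiles(a)
        med_p, q1_p, q3_p = _quartiles(b)
        res = mann_whitney_u(a, b)
        rows.append(
            {
                "feature": col,
                "median_neg": med_n,
                "q1_neg": q1_n,
                "q3_neg": q3_n,
                "median_pos": med_p,
                "q1_pos": q1_p,
                "q3_pos": q3_p,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CategoricalComparison:
    feature: str
    table: pd.DataFrame  # rows: levels; columns: negative, positive, pct within level
    p_value: float | None
    skipped: bool = False
    note: str = ""


def compare_categorical(cohort: CohortTable) -> dict[str, CategoricalComparison]:
    """Category-by-LN-status counts with within-level row percentages and chi-square p.

    A feature observed at a single level is flagged and its test skipped.
    Optional features (t_stage, location) are compared on complete cases.
    """
    frame = cohort.frame
    if cohort.n_negative == 0 or cohort.n_positive == 0:
        raise ValueError("both LN groups must be present")
    out: dict[str, CategoricalComparison] = {}
    for feature, levels in _CATEGORICALS.items():
        sub = frame[frame[feature].notna()]
        counts = pd.DataFrame(
            {
                "negative": [
                    int(((sub[feature] == lev) & (sub["ln_status"] == "negative")).sum())
                    for lev in levels
                ],
                "positive": [
                    int(((sub[feature] == lev) & (sub["ln_status"] == "positive")).sum())
                    for lev in levels
                ],
            },
            index=list(levels),
        )
        counts["total"] = counts["negative"] + counts["positive"]
        with np.errstate(invalid="ignore"):
            counts["pct_negative"] = 100.0 * counts["negative"] / counts["total"]
            counts["pct_positive"] = 100.0 * counts["positive"] / counts["total"]
        observed = counts[counts["total"] > 0]
        if len(observed) < 2:
            out[feature] = CategoricalComparison(
                feature, counts, None, skipped=True,
                note="single observed level; chi-square skipped",
            )
            continue
        res = chi2_independence(observed[["negative", "positive"]].to_numpy())
        out[feature] = CategoricalComparison(feature, counts, res.p_value)
    return out


def feature_roc_table(
    cohort: CohortTable,
    level: float = 0.95,
    fixed_cutoffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-feature ROC analysis of all 17 quantitative SWE parameters.

    Direction is "suspicious if low" for every feature (lower stiffness flags
    metastasis, matching the reported "<= cutoff" convention).  Cutoffs are
    chosen by Youden's index unless ``fixed_cutoffs`` pins a feature to a
    pre-specified threshold.  The returned (cutoff, sens, spec) triples are
    self-consistent: re-applying the cutoff to the cohort reproduces them.
    """
    neg, pos = _split_groups(cohort)
    y = cohort.outcome
    rows = []
    for col in QUANT_COLUMNS:
        x = cohort.frame[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                {
                    "feature": col, "cutoff": np.nan,
                    "sens": np.nan, "sens_low": np.nan, "sens_high": np.nan,
                    "spec": np.nan, "spec_low": np.nan, "spec_high": np.nan,
                    "auc": 0.5, "auc_low": np.nan, "auc_high": np.nan,
                    "p_value": np.nan, "flagged": True,
                }
            )
            continue
        curve = roc_points(x, y, direction="suspicious_if_low")
        if fixed_cutoffs and col in fixed_cutoffs:
            cutoff = float(fixed_cutoffs[col])
            sens = float((pos[col] <= cutoff).mean())
            spec = float((neg[col] > cutoff).mean())
        else:
            cutoff, sens, spec = youden_cutoff(curve)
        # AUC of the low-is-suspicious feature = rank AUC of the negated score
        auc, auc_lo, auc_hi, p_auc = delong_auc_ci(-x, y, level=level)
        k_s = int(round(sens * len(pos)))
        k_p = int(round(spec * len(neg)))
        s_lo, s_hi = clopper_pearson_ci(k_s, len(pos), level)
        sp_lo, sp_hi = clopper_pearson_ci(k_p, len(neg), level)
        rows.append(
            {
                "feature": col, "cutoff": cutoff,
                "sens": sens, "sens_low": s_lo, "sens_high": s_hi,
                "spec": spec, "spec_low": sp_lo, "spec_high": sp_hi,
                "auc": auc, "auc_low": auc_lo, "auc_high": auc_hi,
                "p_value": p_auc, "flagged": False,
            }
        )
    return pd.DataFrame(rows)
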