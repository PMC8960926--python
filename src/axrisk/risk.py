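"""Construction and comparison of the three LN-metastasis risk scores.

Four suspicious features dichotomize each patient: BI-RADS category 5; tumor
E_min <= 3.31 kPa; 3 mm-shell E_min <= 3.52 kPa; stiff-rim sign present.
From the resulting flags three scores are built: the logistic regression
linear predictor, an integer-weighted sum (weights = odds ratios rounded
half-up, floored at 1), and the plain count of suspicious features — the 0-4
risk grade.  When all weights coincide, weighting and counting are order
isomorphic and share every rank-based diagnostic metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .stats import (
    LogisticFitResult,
    clopper_pearson_ci,
    delong_auc_ci,
    delong_paired,
    fit_logistic,
    roc_points,
    youden_cutoff,
)

__all__ = [
    "Rule",
    "DichotomizationRuleSet",
    "published_default_rules",
    "default_rules",
    "apply_rules",
    "fit_final_model",
    "weights_from_ors",
    "score_patients",
    "evaluate_methods",
    "RiskScores",
    "MethodEvaluation",
]


@dataclass(frozen=True)
class Rule:
    """One dichotomization rule: the feature is suspicious when the predicate holds.

    ``op`` is ``"le"`` (value <= threshold, inclusive — "no more than") for
    quantitative features or ``"eq"`` (value == threshold) for categoricals.
    """

    name: str
    feature: str
    op: str
    threshold: object

    def __post_init__(self) -> None:
        if self.op not in ("le", "eq"):
            raise ValueError(f"unknown operator {self.op!r}")

    def evaluate(self, values: pd.Series) -> np.ndarray:
        if self.op == "le":
            return (pd.to_numeric(values) <= float(self.threshold)).to_numpy()
        return (values.astype(str) == str(self.threshold)).to_numpy()


@dataclass(frozen=True)
class DichotomizationRuleSet:
    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule set must be nonempty")
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("rule names must be unique")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rules]

    def to_text(self) -> str:
        lines = [f"{r.name}\t{r.feature}\t{r.op}\t{r.threshold}" for r in self.rules]
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text(), encoding="utf-8")
        return path

    @classmethod
    def from_text(cls, text: str) -> "DichotomizationRuleSet":
        rules = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, feature, op, threshold = line.split("\t")
            rules.append(
                Rule(name, feature, op, float(threshold) if op == "le" else threshold)
            )
        return cls(tuple(rules))

    @classmethod
    def load(cls, path) -> "DichotomizationRuleSet":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


def published_default_rules() -> DichotomizationRuleSet:
    """The four published suspicious-feature rules."""
    return DichotomizationRuleSet(
        (
            Rule("birads5", "birads", "eq", "5"),
            Rule("tumor_emin_low", "tumor_emin", "le", 3.31),
            Rule("shell3_emin_low", "shell3_emin", "le", 3.52),
            Rule("stiff_rim_present", "stiff_rim", "eq", "present"),
        )
    )


default_rules = published_default_rules


def apply_rules(
    cohort: CohortTable, rules: DichotomizationRuleSet | None = None
) -> pd.DataFrame:
    """Per-patient 0/1 suspicious-feature flags (columns = rule names).

    Records missing a rule's feature value are excluded; exclusions are
    recorded on the frame's ``attrs["excluded"]`` as (patient_id, reason).
    """
    rules = rules or published_default_rules()
    frame = cohort.frame
    missing_cols = {r.feature for r in rules.rules} - set(frame.columns)
    if missing_cols:
        raise KeyError(f"rule features absent from cohort: {sorted(missing_cols)}")
    usable = np.ones(len(frame), dtype=bool)
    excluded = []
    for rule in rules.rules:
        na = frame[rule.feature].isna().to_numpy()
        for i in np.flatnonzero(na & usable):
            excluded.append((frame["patient_id"].iloc[i], f"missing {rule.feature}"))
        usable &= ~na
    sub = frame.loc[usable]
    flags = pd.DataFrame(
        {rule.name: rule.evaluate(sub[rule.feature]).astype(int) for rule in rules.rules},
        index=sub["patient_id"].to_numpy(),
    )
    flags.attrs["excluded"] = excluded
    flags.attrs["outcome"] = (sub["ln_status"].to_numpy() == "positive").astype(int)
    return flags


def fit_final_model(
    flags: pd.DataFrame, outcome, alpha: float = 0.05
) -> LogisticFitResult:
    """Multivariate logistic fit of LN status on the suspicious-feature flags.

    All supplied flags enter the model; features with Wald p >= alpha are
    still reported, flagged as not retained via ``result.retained``.
    """
    y = np.asarray(outcome, dtype=int)
    result = fit_logistic(flags.to_numpy(dtype=float), y, names=list(flags.columns))
    non_intercept = slice(1, None)
    result.retained = [
        name
        for name, p in zip(result.names[non_intercept], result.p_values[non_intercept])
        if p < alpha
    ]
    return result


def weights_from_ors(or_values) -> np.ndarray:
    """Integer weights: odds ratios rounded half-up, floored at 1."""
    ors = np.asarray(or_values, dtype=float)
    if np.any(ors <= 0):
        raise ValueError("odds ratios must be positive")
    return np.maximum(1, np.floor(ors + 0.5).astype(int))


@dataclass
class RiskScores:
    """Per-patient scores from the three methods, aligned by subject."""

    regression_lp: np.ndarray
    weighting: np.ndarray
    counting: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "regression": self.regression_lp,
            "weighting": self.weighting,
            "counting": self.counting,
        }


def score_patients(
    flags: pd.DataFrame, fit: LogisticFitResult, weights=None
) -> RiskScores:
    """Compute the regression linear predictor, weighted score, and counting grade.

    The counting grade tallies only the features whose fitted OR exceeds 1;
    with the published rules and cohort all four qualify, making the grade
    run 0-4.  Default weights come from :func:`weights_from_ors`.
    """
    x = flags.to_numpy(dtype=float)
    coefs = fit.coefficients
    if len(coefs) != x.shape[1] + 1:
        raise ValueError("fit does not match flag matrix (expect intercept + flags)")
    ors = fit.or_values[1:]
    if weights is None:
        weights = weights_from_ors(ors)
    weights = np.asarray(weights, dtype=float)
    if weights.size != x.shape[1]:
        raise ValueError("weights length mismatch")
    eligible = (ors > 1).astype(float)
    return RiskScores(
        regression_lp=coefs[0] + x @ coefs[1:],
        weighting=x @ weights,
        counting=(x * eligible).sum(axis=1).astype(int),
    )


@dataclass
class MethodRow:
    method: str
    auc: float
    auc_low: float
    auc_high: float
    cutoff: float
    sens: float
    sens_low: float
    sens_high: float
    spec: float
    spec_low: float
    spec_high: float
    flagged: bool = False


@dataclass
class MethodEvaluation:
    """AUC and Youden operating point per scoring method, plus paired DeLong tests."""

    rows: dict[str, MethodRow]
    pairwise: dict[tuple[str, str], float]  # two-sided DeLong p-values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows.values()]).set_index("method")


def evaluate_methods(
    scores: RiskScores, outcome, level: float = 0.95
) -> MethodEvaluation:
    """Diagnostic performance of each score (higher = more suspicious).

    Per method: tie-corrected rank AUC with DeLong CI, the Youden cutoff on
    the observed score values, and sensitivity/specificity there with exact
    binomial CIs.  Pairwise DeLong tests compare the correlated AUCs.
    """
    y = np.asarray(outcome, dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    rows: dict[str, MethodRow] = {}
    for method, s in scores.as_dict().items():
        s = np.asarray(s, dtype=float)
        if np.ptp(s) == 0:
            rows[method] = MethodRow(method, 0.5, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, np.nan, np.nan, np.nan,
                                     np.nan, flagged=True)
            continue
        auc, lo, hi, _ = delong_auc_ci(s, y, level=level)
        curve = roc_points(s, y, direction="suspicious_if_high")
        cutoff, sens, spec = youden_cutoff(curve)
        k_s = int(round(sens * n_pos))
        k_p = int(round(spec * n_neg))
        s_lo, s_hi = clopper_pearson_ci(k_s, n_pos, level)
        sp_lo, sp_hi = clopper_pearson_ci(k_p, n_neg, level)
        rows[method] = MethodRow(
            method, auc, lo, hi, cutoff, sens, s_lo, s_hi, spec, sp_lo, sp_hi
        )
    pairwise: dict[tuple[str, str], float] = {}
    names = list(scores.as_dict())
    arrs = scores.as_dict()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if rows[a].flagged or rows[b].flagged:
                pairwise[(a, b)] = float("nan")
                continue
            res = delong_paired(arrs[a], arrs[b], y)
            pairwise[(a, b)] = res.p_value
    return MethodEvaluation(rows, pairwise)
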