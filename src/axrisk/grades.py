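"""Grade-wise contingency analysis of the 0-4 risk system.

Per-grade positivity, odds ratios against a chosen (possibly merged)
reference grade set, and the Cochran-Armitage trend test across grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TestResult, cochran_armitage, or_2x2

__all__ = ["GradeContingency", "grade_table", "grade_ors", "trend_test"]


@dataclass(frozen=True)
class GradeContingency:
    """Counts of LN-negative and LN-positive patients per risk grade."""

    neg_counts: tuple[int, ...]
    pos_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.neg_counts) != len(self.pos_counts):
            raise ValueError("neg/pos count vectors must align")
        if any(c < 0 for c in self.neg_counts + self.pos_counts):
            raise ValueError("counts must be nonnegative")

    @property
    def grades(self) -> tuple[int, ...]:
        return tuple(range(len(self.neg_counts)))

    @property
    def n_negative(self) -> int:
        return int(sum(self.neg_counts))

    @property
    def n_positive(self) -> int:
        return int(sum(self.pos_counts))

    @property
    def n_total(self) -> int:
        return self.n_negative + self.n_positive

    def positivity(self) -> np.ndarray:
        """Within-grade fraction of LN-positive patients."""
        neg = np.asarray(self.neg_counts, dtype=float)
        pos = np.asarray(self.pos_counts, dtype=float)
        tot = neg + pos
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, pos / tot, np.nan)
        return frac

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (grade, outcome) arrays whose tabulation equals the counts."""
        grades = []
        outcome = []
        for g, (nn, np_) in enumerate(zip(self.neg_counts, self.pos_counts)):
            grades.extend([g] * (nn + np_))
            outcome.extend([0] * nn + [1] * np_)
        return np.asarray(grades, dtype=int), np.asarray(outcome, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grade": self.grades,
                "negative": self.neg_counts,
                "positive": self.pos_counts,
                "total": [n + p for n, p in zip(self.neg_counts, self.pos_counts)],
                "positivity": self.positivity(),
            }
        )


def grade_table(grades, outcome, n_grades: int | None = None) -> GradeContingency:
    """Tabulate per-patient grades by LN status; empty grades are retained."""
    g = np.asarray(grades, dtype=int)
    y = np.asarray(outcome, dtype=int)
    if g.shape != y.shape:
        raise ValueError("grades and outcome length mismatch")
    if g.size and g.min() < 0:
        raise ValueError("grades must be nonnegative")
    top = int(g.max()) + 1 if g.size else 0
    k = top if n_grades is None else max(n_grades, top)
    neg = np.bincount(g[y == 0], minlength=k)
    pos = np.bincount(g[y == 1], minlength=k)
    return GradeContingency(tuple(int(x) for x in neg), tuple(int(x) for x in pos))


def grade_ors(
    contingency: GradeContingency,
    reference: set[int] | frozenset[int] | tuple[int, ...] = (0,),
    level: float = 0.95,
) -> pd.DataFrame:
    """Odds ratio of each non-reference grade against the pooled reference.

    The reference row carries OR exactly 1 with no interval; other rows carry
    the unadjusted 2x2 cross-product OR, Wald CI, and two-sided p-value.
    """
    ref = frozenset(int(r) for r in reference)
    if not ref:
        raise ValueError("reference grade set must be nonempty")
    unknown = ref - set(contingency.grades)
    if unknown:
        raise ValueError(f"reference grades not in contingency: {sorted(unknown)}")
    ref_pos = sum(contingency.pos_counts[g] for g in ref)
    ref_neg = sum(contingency.neg_counts[g] for g in ref)
    rows = []
    ref_label = "-".join(str(g) for g in sorted(ref))
    rows.append(
        {
            "grade": ref_label,
            "negative": ref_neg,
            "positive": ref_pos,
            "odds_ratio": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
            "reference": True,
        }
    )
    for g in contingency.grades:
        if g in ref:
            continue
        res = or_2x2(
            contingency.pos_counts[g],
            contingency.neg_counts[g],
            ref_pos,
            ref_neg,
            level=level,
        )
        rows.append(
            {
                "grade": str(g),
                "negative": contingency.neg_counts[g],
                "positive": contingency.pos_counts[g],
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "reference": False,
            }
        )
    return pd.DataFrame(rows)


def trend_test(contingency: GradeContingency, scores=None) -> TestResult:
    """Cochran-Armitage trend of LN positivity across grades (scores 0..G)."""
    return cochran_armitage(
        contingency.neg_counts, contingency.pos_counts, scores=scores
    )
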