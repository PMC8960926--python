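"""End-to-end analysis pipeline and published-value verification.

``run_pipeline`` ties the stages together on a cohort CSV or a synthetic
cohort: univariate screening, per-feature ROC, the four-feature logistic
model, the three risk scores and their comparison, the grade-wise
contingency analysis, and a markdown summary — all written as CSV/text under
an output directory, deterministically for a given configuration.

``reproduce_printed`` recomputes every headline statistic that is derivable
exactly from the packaged contingency fixtures (risk-grade AUC and operating
point, grade odds ratios with Wald CIs, positivity by grade, prevalence,
stiff-rim rate, the stiff-rim chi-square, the trend test) and checks each
against its published value at printed precision.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures
from .cohort import CohortTable, expand_contingency, read_cohort, write_cohort
from .grades import GradeContingency, grade_ors, grade_table, trend_test
from .risk import (
    DichotomizationRuleSet,
    apply_rules,
    evaluate_methods,
    fit_final_model,
    published_default_rules,
    score_patients,
    weights_from_ors,
)
from .screening import compare_categorical, compare_continuous, feature_roc_table
from .stats import auc_rank, chi2_independence, clopper_pearson_ci, or_2x2, youden_cutoff, roc_points
from .synthetic import SyntheticConfig, default_config, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_printed", "ReproductionReport"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    input: str | Path = "synthetic"  # cohort CSV path or "synthetic"
    output_dir: str | Path = "axrisk_report"
    rules: str | Path | None = None  # rule file; None = published defaults
    alpha: float = 0.05
    ci_level: float = 0.95
    seed: int = 0
    n_synthetic: int = 10_000
    synthetic: SyntheticConfig | None = None

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if str(config.input) == "synthetic":
        syn = config.synthetic or default_config(config.n_synthetic, seed=config.seed)
        return generate_cohort(syn)
    return read_cohort(config.input)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write all table analogs to ``output_dir``.

    Returns the report directory.  Raises on an invalid configuration or a
    degenerate cohort (a single LN class).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config)
    if len(cohort) == 0 or cohort.n_positive == 0 or cohort.n_negative == 0:
        raise ValueError(
            "degenerate cohort: both LN-positive and LN-negative patients are required"
        )
    rules = (
        DichotomizationRuleSet.load(config.rules)
        if config.rules
        else published_default_rules()
    )

    write_cohort(cohort, out / "cohort.csv")

    categorical = compare_categorical(cohort)
    cat_rows = []
    for feature, comp in categorical.items():
        t = comp.table.copy()
        t.insert(0, "level", t.index)
        t.insert(0, "feature", feature)
        t["p_value"] = comp.p_value
        t["skipped"] = comp.skipped
        cat_rows.append(t)
    pd.concat(cat_rows, ignore_index=True).to_csv(out / "categorical.csv", index=False)

    continuous = compare_continuous(cohort)
    continuous.to_csv(out / "continuous.csv", index=False)

    roc_table = feature_roc_table(cohort, level=config.ci_level)
    roc_table.to_csv(out / "feature_roc.csv", index=False)

    flags = apply_rules(cohort, rules)
    outcome = flags.attrs["outcome"]
    fit = fit_final_model(flags, outcome, alpha=config.alpha)
    fit.summary_frame().to_csv(out / "final_model.csv")

    weights = weights_from_ors(fit.or_values[1:])
    scores = score_patients(flags, fit, weights)
    evaluation = evaluate_methods(scores, outcome, level=config.ci_level)
    evaluation.to_frame().to_csv(out / "method_comparison.csv")
    pd.DataFrame(
        [
            {"method_a": a, "method_b": b, "delong_p": p}
            for (a, b), p in evaluation.pairwise.items()
        ]
    ).to_csv(out / "method_delong.csv", index=False)

    contingency = grade_table(scores.counting, outcome, n_grades=len(rules.rules) + 1)
    contingency.to_frame().to_csv(out / "grade_table.csv", index=False)
    grade_ors(contingency, reference=(0,), level=config.ci_level).to_csv(
        out / "grade_ors_ref0.csv", index=False
    )
    grade_ors(contingency, reference=(1,), level=config.ci_level).to_csv(
        out / "grade_ors_ref1.csv", index=False
    )
    grade_ors(contingency, reference=(0, 1), level=config.ci_level).to_csv(
        out / "grade_ors_ref01.csv", index=False
    )
    trend = trend_test(contingency)

    # positivity-by-grade bar chart data
    contingency.to_frame()[["grade", "positivity"]].to_csv(
        out / "positivity_by_grade.csv", index=False
    )

    counting_row = evaluation.rows["counting"]
    summary = [
        "# LN-metastasis risk grade report",
        "",
        f"Cohort: {cohort.provenance} ({len(cohort)} patients, "
        f"{cohort.n_positive} LN-positive, prevalence "
        f"{cohort.n_positive / len(cohort):.1%})",
        "",
        "## Suspicious-feature model",
        "",
        fit.summary_frame().to_string(),
        "",
        f"Integer weights: {dict(zip(flags.columns, weights.tolist()))}",
        "",
        "## Method comparison",
        "",
        evaluation.to_frame().to_string(),
        "",
        "## Risk grades",
        "",
        contingency.to_frame().to_string(index=False),
        "",
        f"Cochran-Armitage trend: z = {trend.statistic:.3f}, p = {trend.p_value:.3g}",
        "",
        f"Counting-grade AUC {counting_row.auc:.3f} "
        f"({counting_row.auc_low:.3f}-{counting_row.auc_high:.3f}); "
        f"Youden cutoff grade >= {counting_row.cutoff:g}: "
        f"sens {counting_row.sens:.1%}, spec {counting_row.spec:.1%}",
    ]
    (out / "summary.md").write_text("\n".join(summary) + "\n", encoding="utf-8")

    run_log = {
        "seed": config.seed,
        "alpha": config.alpha,
        "ci_level": config.ci_level,
        "input": str(config.input),
        "n_patients": len(cohort),
        "rules": [vars(r) for r in rules.rules],
        "weights": [int(w) for w in weights],
        "settings": {
            "or_rounding": "round half up, floor 1",
            "proportion_ci": "Clopper-Pearson exact",
            "or_ci": "Wald on log scale, z = 1.959964",
            "auc_comparison": "DeLong paired",
            "youden_ties": "higher sensitivity, then lower threshold",
            "logistic": "IRLS, tol 1e-10, max 100 iterations",
        },
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2) + "\n", encoding="utf-8"
    )
    return out


# ---------------------------------------------------------------------------
# Reproduction of published values from the contingency fixtures
# ---------------------------------------------------------------------------

@dataclass
class Check:
    name: str
    computed: float
    printed: float
    passed: bool
    kind: str = "eq"  # eq at printed precision, or "lt" bound


@dataclass
class ReproductionReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_text(self) -> str:
        lines = ["published-value reproduction"]
        for c in self.checks:
            mark = "PASS" if c.passed else "FAIL"
            rel = "<" if c.kind == "lt" else "vs"
            lines.append(
                f"  [{mark}] {c.name:<38s} computed {c.computed:.6g} {rel} printed {c.printed:g}"
            )
        lines.append("all checks passed" if self.all_pass else "SOME CHECKS FAILED")
        return "\n".join(lines)


def _round_to(x: float, printed: float) -> float:
    """Round ``x`` to the decimal precision at which ``printed`` is stated."""
    s = f"{printed:g}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return round(x, decimals)


def reproduce_printed(
    contingency: GradeContingency | None = None,
    stiff_rim_2x2=None,
) -> ReproductionReport:
    """Recompute the fixture-derivable headline statistics and verify them.

    Optional arguments substitute alternative contingency tables (used to
    confirm the harness fails when a count is tampered with).
    """
    gc = contingency or fixtures.GRADE_CONTINGENCY
    rim = np.asarray(
        fixtures.STIFF_RIM_2X2 if stiff_rim_2x2 is None else stiff_rim_2x2
    )
    report = ReproductionReport()

    def check_eq(name: str, computed: float, printed: float) -> None:
        report.checks.append(
            Check(name, computed, printed, _round_to(computed, printed) == printed)
        )

    def check_lt(name: str, computed: float, bound: float) -> None:
        report.checks.append(Check(name, computed, bound, computed < bound, kind="lt"))

    grades, outcome = expand_contingency(gc)
    auc = auc_rank(grades, outcome)
    check_eq("counting-grade AUC", auc, 0.656)

    curve = roc_points(grades.astype(float), outcome, direction="suspicious_if_high")
    _, sens, spec = youden_cutoff(curve)
    check_eq("sensitivity at Youden cutoff (%)", sens * 100, 54.60)
    check_eq("specificity at Youden cutoff (%)", spec * 100, 68.99)

    n_pos, n_neg = gc.n_positive, gc.n_negative
    s_lo, s_hi = clopper_pearson_ci(int(round(sens * n_pos)), n_pos)
    check_eq("sensitivity CI low (%)", s_lo * 100, 46.9)
    check_eq("sensitivity CI high (%)", s_hi * 100, 62.1)
    sp_lo, sp_hi = clopper_pearson_ci(int(round(spec * n_neg)), n_neg)
    check_eq("specificity CI low (%)", sp_lo * 100, 64.5)
    check_eq("specificity CI high (%)", sp_hi * 100, 73.3)

    printed_ors = {1: 3.095, 2: 4.211, 3: 7.172, 4: 18.318}
    printed_cis = {
        1: (0.896, 10.696),
        2: (1.243, 14.271),
        3: (2.132, 24.132),
        4: (5.016, 66.892),
    }
    table0 = grade_ors(gc, reference=(0,)).set_index("grade")
    for g, orv in printed_ors.items():
        row = table0.loc[str(g)]
        check_eq(f"grade {g} vs 0 OR", row["odds_ratio"], orv)
        check_eq(f"grade {g} vs 0 CI low", row["ci_low"], printed_cis[g][0])
        check_eq(f"grade {g} vs 0 CI high", row["ci_high"], printed_cis[g][1])

    table1 = grade_ors(gc, reference=(1,)).set_index("grade")
    for g, (orv, lo, hi) in {
        2: (1.361, 0.810, 2.286),
        3: (2.317, 1.403, 3.827),
        4: (5.918, 3.010, 11.636),
    }.items():
        row = table1.loc[str(g)]
        check_eq(f"grade {g} vs 1 OR", row["odds_ratio"], orv)
        check_eq(f"grade {g} vs 1 CI low", row["ci_low"], lo)
        check_eq(f"grade {g} vs 1 CI high", row["ci_high"], hi)

    table01 = grade_ors(gc, reference=(0, 1)).set_index("grade")
    for g, (orv, lo, hi) in {
        2: (1.620, 0.982, 2.671),
        3: (2.759, 1.703, 4.469),
        4: (7.045, 3.634, 13.659),
    }.items():
        row = table01.loc[str(g)]
        check_eq(f"grade {g} vs 0-1 OR", row["odds_ratio"], orv)
        check_eq(f"grade {g} vs 0-1 CI low", row["ci_low"], lo)
        check_eq(f"grade {g} vs 0-1 CI high", row["ci_high"], hi)

    positivity = gc.positivity() * 100
    for g, printed in enumerate([7.1, 19.2, 24.5, 35.6, 58.5]):
        check_eq(f"grade {g} positivity (%)", float(positivity[g]), printed)

    check_eq("prevalence (%)", 100 * n_pos / gc.n_total, 28.1)
    check_eq("stiff-rim rate among positives (%)", 100 * rim[0, 1] / rim[:, 1].sum(), 82.2)

    chi = chi2_independence(rim)
    check_lt("stiff-rim chi-square p", chi.p_value, 0.001)
    trend = trend_test(gc)
    check_lt("Cochran-Armitage trend p", trend.p_value, 0.0001)
    return report
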