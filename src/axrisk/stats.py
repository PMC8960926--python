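"""Statistical primitives for diagnostic-accuracy and risk-grade analysis.

Everything here is implemented from first principles (rank formulas, IRLS,
placement-value covariances) so that each estimator is auditable against a
closed-form or brute-force oracle; SciPy is used only for reference
distributions (normal, chi-square, beta quantiles) and mid-rank computation.

Conventions
-----------
* Two-sided p-values throughout; alpha and confidence level are the caller's
  concern.
* Binary outcomes are coded 1 = event (positive lymph node), 0 = non-event.
* Odds-ratio confidence intervals are Wald intervals on the log scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "RocCurve",
    "LogisticFitResult",
    "OddsRatioResult",
    "DelongResult",
    "mann_whitney_u",
    "chi2_independence",
    "auc_rank",
    "roc_points",
    "youden_cutoff",
    "clopper_pearson_ci",
    "or_2x2",
    "fit_logistic",
    "delong_paired",
    "delong_auc_ci",
    "cochran_armitage",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC operating points, one per observed threshold.

    ``direction`` states which tail of the score is suspicious:
    ``suspicious_if_low`` means the test is positive when score <= threshold
    (the convention used for stiffness minima, reported as "<= cutoff"),
    ``suspicious_if_high`` means positive when score >= threshold.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    direction: str

    def youden(self) -> np.ndarray:
        return self.sens + self.spec - 1.0


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


@dataclass
class LogisticFitResult:
    """Maximum-likelihood logistic fit with Wald inference per feature."""

    names: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    or_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float
    separation: bool = False

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "odds_ratio": self.or_values,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            },
            index=self.names,
        )


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return arr


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample ``a`` using mid-ranks."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    a, b, *, continuity: bool = False, exact_max_n: int = 8
) -> TestResult:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    The U statistic is reported for the first sample.  When both samples
    contain at most ``exact_max_n`` observations the p-value is computed by
    exhaustive enumeration of all label assignments of the pooled values;
    otherwise a normal approximation with tie-corrected variance is used.
    ``continuity`` toggles a 0.5 continuity correction on the z statistic
    (off by default).
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = range(pooled.size)
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return TestResult(u_obs, count / total, "mann-whitney-exact")

    pooled = np.concatenate([a, b])
    n = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u_obs, 1.0, "mann-whitney-normal")
    diff = u_obs - mu
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return TestResult(u_obs, min(p, 1.0), "mann-whitney-normal")


def chi2_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal row/column")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return TestResult(stat, p, "pearson-chi2", df=df)


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).ravel()
    uniq = np.unique(y)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    if uniq.size < 2:
        raise ValueError("both outcome classes must be present")
    return y.astype(int)


def auc_rank(scores, labels) -> float:
    """Tie-corrected rank AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed from mid-ranks in O(n log n); higher scores are treated as more
    suspicious.
    """
    s = _as_1d(scores, "scores")
    y = _check_binary(labels)
    if s.size != y.size:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels, direction: str = "suspicious_if_high") -> RocCurve:
    """Empirical ROC curve with one point per distinct observed value.

    A sentinel threshold (+/- infinity depending on direction) is prepended so
    the curve always contains the (sens, spec) extremes (0, 1) and (1, 0).
    """
    if direction not in ("suspicious_if_high", "suspicious_if_low"):
        raise ValueError(f"unknown direction {direction!r}")
    s = _as_1d(scores, "scores")
    y = _check_binary(labels)
    if s.size != y.size:
        raise ValueError("scores and labels length mismatch")
    pos = s[y == 1]
    neg = s[y == 0]

    if direction == "suspicious_if_low":
        # test positive when value <= threshold
        values = np.unique(s)
        sens = np.searchsorted(np.sort(pos), values, side="right") / pos.size
        spec = 1.0 - np.searchsorted(np.sort(neg), values, side="right") / neg.size
        thresholds = np.concatenate([[-np.inf], values])
    else:
        # test positive when value >= threshold
        values = np.unique(s)[::-1]
        sens = 1.0 - np.searchsorted(np.sort(pos), values, side="left") / pos.size
        spec = np.searchsorted(np.sort(neg), values, side="left") / neg.size
        thresholds = np.concatenate([[np.inf], values])

    sens = np.concatenate([[0.0], sens])
    spec = np.concatenate([[1.0], spec])
    return RocCurve(thresholds, sens, spec, direction)


def roc_auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the (1-spec, sens) polyline."""
    fpr = 1.0 - curve.spec
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sens[order], fpr[order]))


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sens + spec - 1.

    Ties on J are broken toward higher sensitivity, then the lower threshold.
    The sentinel extreme is never returned unless it is the unique maximum.
    """
    j = curve.youden()
    # lexicographic: J desc, sens desc, threshold asc
    order = np.lexsort((curve.thresholds, -curve.sens, -j))
    best = order[0]
    if not np.isfinite(curve.thresholds[best]):
        finite = np.isfinite(curve.thresholds)
        if finite.any():
            jmax = j[best]
            cand = np.flatnonzero(finite & (j >= jmax - 1e-15))
            if cand.size:
                sub = np.lexsort(
                    (curve.thresholds[cand], -curve.sens[cand], -j[cand])
                )
                best = cand[sub[0]]
    return (
        float(curve.thresholds[best]),
        float(curve.sens[best]),
        float(curve.spec[best]),
    )


# ---------------------------------------------------------------------------
# Proportions and odds ratios
# ---------------------------------------------------------------------------

def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid k={k}, n={n}")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def or_2x2(
    exp_pos: float,
    exp_neg: float,
    ref_pos: float,
    ref_neg: float,
    level: float = 0.95,
) -> OddsRatioResult:
    """Cross-product odds ratio of the exposed vs reference arm.

    The Wald interval is exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to all four
    cells), flagged via ``corrected``; a fully empty arm is undefined.
    """
    cells = np.array([exp_pos, exp_neg, ref_pos, ref_neg], dtype=float)
    if np.any(cells < 0):
        raise ValueError("counts must be nonnegative")
    if (exp_pos == 0 and exp_neg == 0) or (ref_pos == 0 and ref_neg == 0):
        raise ValueError("one arm of the 2x2 table is empty; OR undefined")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    p = 2.0 * norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        math.exp(log_or),
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
        float(p),
        corrected,
    )


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

def fit_logistic(
    design,
    outcome,
    names: list[str] | None = None,
    *,
    add_intercept: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    level: float = 0.95,
) -> LogisticFitResult:
    """Binary logistic regression by iteratively reweighted least squares.

    Converges when the log-likelihood change falls below ``tol``.  Complete or
    quasi-complete separation is detected via a diverging coefficient norm and
    reported (``separation``/``converged`` flags); affected Wald intervals are
    unbounded.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _check_binary(outcome).astype(float)
    if X.shape[0] != y.size:
        raise ValueError("design and outcome length mismatch")
    const_cols = np.ptp(X, axis=0) == 0
    if const_cols.any() and not add_intercept:
        pass  # explicit intercept column supplied by caller
    elif const_cols.any():
        raise ValueError("constant feature column in design")

    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    separation = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-12)
        z_work = eta + (y - p) / w
        xtw = X.T * w
        try:
            beta = np.linalg.solve(xtw @ X, xtw @ z_work)
        except np.linalg.LinAlgError:
            separation = True
            break
        eta = np.clip(X @ beta, -500, 500)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if np.linalg.norm(beta) > 1e4 or not np.isfinite(ll):
            separation = True
            break
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    # separation drives some |log-odds| coefficient beyond any plausible scale
    if np.any(np.abs(beta) > 20):
        separation = True
        converged = False

    eta = np.clip(X @ beta, -500, 500)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1.0 - p), 1e-12)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.inf)
    if separation:
        se = np.full(X.shape[1], np.inf)

    zcrit = norm.ppf(1.0 - (1.0 - level) / 2.0)
    with np.errstate(over="ignore", invalid="ignore"):
        or_vals = np.exp(beta)
        ci_low = np.exp(beta - zcrit * se)
        ci_high = np.exp(beta + zcrit * se)
        zstat = np.where(se > 0, beta / se, np.inf)
        p_vals = 2.0 * norm.sf(np.abs(zstat))
    return LogisticFitResult(
        names=names,
        coefficients=beta,
        se=se,
        or_values=or_vals,
        ci_low=ci_low,
        ci_high=ci_high,
        p_values=p_vals,
        converged=converged and not separation,
        n_iter=it,
        log_likelihood=ll_old if np.isfinite(ll_old) else float("nan"),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# DeLong AUC inference
# ---------------------------------------------------------------------------

def delong_paired(scores_a, scores_b, labels) -> DelongResult:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns both AUCs, the variance of their difference from the
    placement-value covariance estimator, and a two-sided z test.
    """
    sa = _as_1d(scores_a, "scores_a")
    sb = _as_1d(scores_b, "scores_b")
    y = _check_binary(labels)
    if sa.size != sb.size or sa.size != y.size:
        raise ValueError("scores and labels length mismatch")
    # positives/negatives pair across curves via the shared subject order
    v10a, v01a = _placements_unsorted(sa, y)
    v10b, v01b = _placements_unsorted(sb, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m = v10a.size
    n = v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if abs(diff) < 1e-15 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(var), float(z), float(p))


def _placements_unsorted(scores: np.ndarray, y: np.ndarray):
    """Placement values keeping the original subject order within classes."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    neg_sorted = np.sort(neg)
    below = np.searchsorted(neg_sorted, pos, side="left")
    ties = np.searchsorted(neg_sorted, pos, side="right") - below
    v10 = (below + 0.5 * ties) / neg.size
    pos_sorted = np.sort(pos)
    above = pos.size - np.searchsorted(pos_sorted, neg, side="right")
    ties_n = np.searchsorted(pos_sorted, neg, side="right") - np.searchsorted(
        pos_sorted, neg, side="left"
    )
    v01 = (above + 0.5 * ties_n) / pos.size
    return v10, v01


def delong_variance(scores, labels) -> float:
    """Single-curve DeLong variance of the rank AUC."""
    s = _as_1d(scores, "scores")
    y = _check_binary(labels)
    v10, v01 = _placements_unsorted(s, y)
    if v10.size < 2 or v01.size < 2:
        raise ValueError("need at least two subjects per class")
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def delong_auc_ci(scores, labels, level: float = 0.95):
    """AUC with DeLong normal-approximation CI and a test of AUC != 0.5."""
    auc = auc_rank(scores, labels)
    var = delong_variance(scores, labels)
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    half = z * math.sqrt(var)
    if var > 0:
        p = 2.0 * norm.sf(abs(auc - 0.5) / math.sqrt(var))
    else:
        p = 1.0 if abs(auc - 0.5) < 1e-15 else 0.0
    return auc, max(auc - half, 0.0), min(auc + half, 1.0), float(p)


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

def cochran_armitage(neg_counts, pos_counts, scores=None) -> TestResult:
    """Cochran-Armitage trend test for a binary outcome over ordered groups.

    ``scores`` defaults to 0, 1, ..., G.  The z statistic uses the pooled
    binomial variance; for two groups z^2 equals the Pearson chi-square of the
    corresponding 2x2 table.
    """
    neg = np.asarray(neg_counts, dtype=float)
    pos = np.asarray(pos_counts, dtype=float)
    if neg.shape != pos.shape or neg.ndim != 1:
        raise ValueError("neg_counts and pos_counts must be 1-d and aligned")
    if neg.size < 2:
        raise ValueError("need at least two grades for a trend test")
    if np.any(neg < 0) or np.any(pos < 0):
        raise ValueError("counts must be nonnegative")
    s = np.arange(neg.size, dtype=float) if scores is None else np.asarray(
        scores, dtype=float
    )
    if s.size != neg.size:
        raise ValueError("scores length mismatch")
    n = neg + pos
    n_tot = n.sum()
    r_tot = pos.sum()
    if n_tot == 0 or r_tot == 0 or r_tot == n_tot:
        raise ValueError("both outcome classes must be present")
    pbar = r_tot / n_tot
    t_stat = float((pos * s).sum() - r_tot * (n * s).sum() / n_tot)
    var = pbar * (1 - pbar) * float((n * s**2).sum() - (n * s).sum() ** 2 / n_tot)
    if var <= 0:
        return TestResult(0.0, 1.0, "cochran-armitage")
    z = t_stat / math.sqrt(var)
    return TestResult(z, float(2.0 * norm.sf(abs(z))), "cochran-armitage")
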