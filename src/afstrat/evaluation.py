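"""Statistical evaluation machinery.

Outcome-stratified 80/20 splitting, ROC analysis with DeLong confidence
intervals and paired AUC comparison, confusion-matrix metrics with Wilson
intervals, and the univariate tests used for baseline tables (Pearson
chi-square, two-proportion z, Welch t).

The DeLong estimator is the standard nonparametric variance/covariance of
the Mann-Whitney AUC built from per-case placement values (computed with
midranks, O(n log n)); the paired test compares two scores evaluated on
the same cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

__all__ = [
    "SplitPlan",
    "RocResult",
    "stratified_split",
    "roc_auc_delong",
    "delong_compare",
    "chi_square_independence",
    "two_proportion_z",
    "two_sample_t",
    "format_count_pct",
    "cohort_summary",
]


@dataclass
class SplitPlan:
    """Disjoint, exhaustive train/test indices preserving outcome mix."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        tr, te = set(self.train_ids.tolist()), set(self.test_ids.tolist())
        if tr & te:
            raise ValueError("train and test overlap")


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    auc_se: float
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")
        lo, hi = self.ci95
        if not lo <= self.auc <= hi:
            raise ValueError("AUC outside its confidence interval")


def stratified_split(cohort: pd.DataFrame, seed: int, test_fraction: float = 0.2,
                     outcome_col: str = "outcome_1y") -> SplitPlan:
    """Outcome-stratified 80/20 split, reproducible under ``seed``.

    The test arm receives round(test_fraction * n) patients overall (so 204
    patients split 163/41), allocated per outcome class by largest-
    remainder apportionment — class proportions in each arm match the whole
    cohort within one patient.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError("need n >= 10")
    y = cohort[outcome_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class cohort cannot be stratified")
    n_test = int(round(test_fraction * n))
    # largest-remainder apportionment of the test arm across classes
    exact = counts * n_test / n
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n_test - base.sum()
    order = np.argsort(-rem)
    base[order[:short]] += 1

    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, k in zip(classes, base):
        members = np.flatnonzero(y == cls)
        test_idx.append(rng.choice(members, size=k, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return SplitPlan(train_ids=train_idx, test_ids=test_idx, test_fraction=test_fraction)


# --- DeLong machinery ------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Per-case placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    auc = v10.mean()
    return auc, v10, v01


def roc_auc_delong(scores, labels, threshold: float | None = None) -> RocResult:
    """ROC AUC with DeLong variance and confusion metrics at a threshold.

    The AUC is the Mann-Whitney statistic (ties count one half); its 95% CI
    uses the DeLong variance with a normal approximation, clipped to
    [0, 1]. Confusion metrics (sensitivity, specificity, PPV, NPV) are
    evaluated at Youden's J-optimal threshold unless one is supplied, with
    Wilson 95% intervals. Constant scores yield AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUC defaults to 0.5", stacklevel=2)
        auc, se = 0.5, 0.0
        v10 = v01 = None
    else:
        auc, v10, v01 = _placements(scores, labels)
        var = (np.var(v10, ddof=1) / len(v10)) + (np.var(v01, ddof=1) / len(v01))
        se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    if threshold is None:
        threshold = _youden_threshold(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))

    def rate(num, den):
        if den == 0:
            return 0.0, (0.0, 1.0)
        lo, hi = proportion_confint(num, den, method="wilson")
        return num / den, (float(lo), float(hi))

    sens, sens_ci = rate(tp, tp + fn)
    spec, spec_ci = rate(tn, tn + fp)
    ppv, ppv_ci = rate(tp, tp + fp)
    npv, npv_ci = rate(tn, tn + fn)
    return RocResult(
        auc=float(auc), ci95=(float(ci[0]), float(ci[1])), auc_se=se,
        threshold=float(threshold),
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        ppv=ppv, ppv_ci=ppv_ci, npv=npv, npv_ci=npv_ci,
    )


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    cand = np.unique(scores)
    best_t, best_j = cand[0], -np.inf
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    for t in cand:
        pred = scores >= t
        sens = np.sum(pred & pos) / n_pos
        spec = np.sum(~pred & ~pos) / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two AUCs on the same cases.

    Returns ``(auc_a, auc_b, p)`` with a two-sided p-value; identical score
    vectors give a zero difference and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must share one length")
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


# --- univariate tests ------------------------------------------------------


def chi_square_independence(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square independence test on a 2x2 count table.

    No continuity correction by default. Returns (statistic, p).
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table_f = np.asarray(table, dtype=float)
        if np.any(table_f < 0) or np.any(table_f != np.round(table_f)):
            raise ValueError("counts must be nonnegative integers")
        table = table_f.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z-test (pooled); returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("zero denominator")
    if x1 / n1 == x2 / n2:
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p)


def two_sample_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Student's t-test for two samples (Welch variant by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def format_count_pct(count: int, total: int) -> str:
    """Baseline-table cell: count with integer percentage, e.g. ``88 (78%)``."""
    pct = 0 if total == 0 else round(100.0 * count / total)
    return f"{count} ({pct:.0f}%)"


def cohort_summary(cohort: pd.DataFrame, variables: list[str] | None = None,
                   outcome_col: str = "outcome_1y") -> pd.DataFrame:
    """Per-category counts and percentages, overall and by outcome.

    Mirrors the layout of a clinical baseline table: one row per category
    of each categorical variable with columns for all patients, the
    freedom-from-AF arm and the AF-recurrence arm, each formatted as
    ``count (pct%)``.
    """
    if variables is None:
        variables = [c for c in ("af_type", "treatment", "treatment_class")
                     if c in cohort.columns]
    free = cohort[cohort[outcome_col] == 1]
    recur = cohort[cohort[outcome_col] == 0]
    rows = []
    for var in variables:
        for level in sorted(cohort[var].astype(str).unique()):
            rows.append(
                {
                    "variable": var,
                    "category": level,
                    "all_patients": format_count_pct(
                        int((cohort[var].astype(str) == level).sum()), len(cohort)),
                    "af_freedom": format_count_pct(
                        int((free[var].astype(str) == level).sum()), len(free)),
                    "af": format_count_pct(
                        int((recur[var].astype(str) == level).sum()), len(recur)),
                }
            )
    return pd.DataFrame(rows)
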