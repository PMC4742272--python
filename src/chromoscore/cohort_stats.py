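"""Cohort-level statistics: group comparisons, outcome contingency analysis,
ROC/AUC with DeLong confidence intervals, and interobserver ICC.

These are the standard tools used to evaluate a prognostic marker on a
two-group cohort: Student's t / Mann-Whitney U for continuous covariates,
chi-square or Fisher's exact test for the 2x2 outcome table, the empirical
ROC curve with a DeLong 95% CI for discriminative ability, and the
two-way-random absolute-agreement single-measures intraclass correlation,
ICC(2,1), for interobserver reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "RocResult",
    "compare_continuous",
    "event_rate_test",
    "roc_auc",
    "icc_agreement",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of (event, no event) per group; rows are groups."""

    a: int  # group 1, event
    b: int  # group 1, no event
    c: int  # group 2, event
    d: int  # group 2, no event

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC and a DeLong 95% confidence interval."""

    auc: float
    ci_lo: float
    ci_hi: float
    curve: np.ndarray  # (n_points, 2) of (FPR, TPR)
    orientation: str  # "low" | "high": score direction that predicts events

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.auc <= self.ci_hi):
            raise ValueError("confidence bounds must bracket the AUC")


# ---------------------------------------------------------------------------
# continuous two-sample comparison


def _round_half_up_pct(numer: int, denom: int) -> int:
    return int(np.floor(100.0 * numer / denom + 0.5))


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Handles ties; feasible for small samples (the pooled combinations are
    enumerated exhaustively).  Returns (U of x, p).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mu)
    total = comb(n1 + n2, n1)
    extreme = sum(
        1
        for idx in combinations(range(n1 + n2), n1)
        if abs(u_of(idx) - mu) >= dev - 1e-12
    )
    return u_obs, extreme / total


def compare_continuous(
    x, y, method: str = "mann_whitney"
) -> tuple[float, float]:
    """Two-sided two-sample comparison.

    ``method="t"`` runs Student's t with pooled variance; ``"mann_whitney"``
    runs the U test — exact enumeration for small samples (both arms <= 9,
    tie-safe), the tie-corrected normal approximation otherwise.  Returns
    ``(statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if method == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("zero variance in both samples: t is undefined")
        res = stats.ttest_ind(x, y, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        if max(len(x), len(y)) <= 9:
            return _exact_mannwhitney(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# 2x2 outcome table


def event_rate_test(
    tbl: ContingencyTable2x2, method: str = "fisher"
) -> dict:
    """Event rates per group and a two-sided test of their difference.

    Percentages are rounded half-up to integers (presentation convention for
    clinical outcome tables).  ``method="chi_square"`` uses the df=1
    chi-square without continuity correction; ``"fisher"`` (default,
    appropriate when a cell expectation is < 5) enumerates the
    hypergeometric distribution.  Returns a dict with per-group rates, the
    statistic and the p-value.
    """
    arr = tbl.as_array()
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise ValueError("table has a zero margin; test undefined")
    rate1 = _round_half_up_pct(tbl.a, tbl.a + tbl.b)
    rate2 = _round_half_up_pct(tbl.c, tbl.c + tbl.d)
    if method == "chi_square":
        res = stats.chi2_contingency(arr, correction=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "fisher":
        statistic, p = stats.fisher_exact(arr, alternative="two-sided")
        statistic, p = float(statistic), float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "rate_group1_pct": rate1,
        "rate_group2_pct": rate2,
        "statistic": statistic,
        "p": p,
        "method": method,
    }


# ---------------------------------------------------------------------------
# ROC / AUC


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "low":
        return -scores
    if orientation == "high":
        return scores
    raise ValueError("orientation must be 'low' or 'high'")


def roc_auc(scores, events, orientation: str = "low") -> RocResult:
    """Empirical ROC analysis of a prognostic score.

    ``orientation`` states which direction of the raw score predicts an
    event ("low": smaller scores in event patients, the convention for the
    chromatin scores).  The AUC is the all-pairs concordance (ties count
    half, equivalently the normalized Mann-Whitney U) and the 95% CI comes
    from DeLong's structural-components variance estimate, truncated to
    [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=bool)
    if scores.shape != events.shape or scores.ndim != 1:
        raise ValueError("scores and events must be matching 1-D arrays")
    pos = _oriented(scores[events], orientation)  # event class
    neg = _oriented(scores[~events], orientation)
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")

    # structural components (DeLong): psi = 1 if pos > neg, 0.5 if tied
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-event component
    v01 = psi.mean(axis=0)  # per-control component
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    ci_lo = float(np.clip(auc - half, 0.0, 1.0))
    ci_hi = float(np.clip(auc + half, 0.0, 1.0))

    # empirical curve over all thresholds of the oriented score
    oriented_all = _oriented(scores, orientation)
    order = np.argsort(-oriented_all, kind="stable")
    sorted_scores = oriented_all[order]
    sorted_events = events[order]
    tps = np.cumsum(sorted_events)
    fps = np.cumsum(~sorted_events)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / m]
    fpr = np.r_[0.0, fps[distinct] / n]
    curve = np.column_stack([fpr, tpr])
    return RocResult(
        auc=auc, ci_lo=min(ci_lo, auc), ci_hi=max(ci_hi, auc),
        curve=curve, orientation=orientation,
    )


# ---------------------------------------------------------------------------
# intraclass correlation


def icc_agreement(ratings, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Interobserver agreement: ICC(2,1) with an F-based confidence interval.

    ``ratings`` is an n-subjects x k-raters grid (complete, n >= 3, k >= 2).
    The two-way random-effects, absolute-agreement, single-measures form is
    computed from the two-way ANOVA mean squares; the CI follows the
    standard Satterthwaite F approximation.  Returns
    ``(icc, (ci_lo, ci_hi))``.
    """
    grid = np.asarray(ratings, dtype=float)
    if grid.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters grid")
    n, k = grid.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 subjects and k >= 2 raters")
    if np.isnan(grid).any():
        raise ValueError("ratings grid must be complete")

    grand = grid.mean()
    row_means = grid.mean(axis=1)
    col_means = grid.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((grid - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # residual

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ratings grid is constant; ICC undefined")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        return 1.0, (1.0, 1.0)  # identical raters: perfect agreement

    # Satterthwaite df for the absolute-agreement single-measures CI
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return icc, (icc, icc)
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else 1.0
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    return float(icc), (min(lo, icc), max(hi, icc))
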