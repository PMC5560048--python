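"""Group-comparison logic: parametric/non-parametric dispatch and mean ± 95% CI.

The comparison convention reproduced here is the common two-branch scheme:

* two groups → Student's t-test when both groups pass a Shapiro–Wilk
  normality check at α = 0.05, otherwise the Mann–Whitney U-test;
* three or more groups → one-way ANOVA when every group passes, otherwise
  the Kruskal–Wallis H-test.

Any single failing group sends the whole comparison to the non-parametric
branch.  Per-group summaries are the mean with the Student-t 95% confidence
interval.  No correction is applied across separate comparisons — each
call is one panel's test, reported on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["StatReport", "GroupSummary", "is_parametric", "compare_groups", "mean_ci95"]

TESTS = ("student_t", "mann_whitney", "anova", "kruskal_wallis")


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class StatReport:
    """Outcome of one group comparison: test choice, statistic, p, summaries."""

    test_used: str
    statistic: float
    p_value: float
    groups: tuple[GroupSummary, ...]

    def __post_init__(self) -> None:
        assert self.test_used in TESTS
        assert 0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)


def is_parametric(sample: Sequence[float], alpha: float = 0.05) -> bool:
    """Shapiro–Wilk normality check: True iff p > alpha.

    Needs n >= 3 (the test is undefined below that).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"normality check needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        return False  # constant sample: Shapiro-Wilk undefined, clearly non-normal
    return bool(stats.shapiro(x).pvalue > alpha)


def mean_ci95(sample: Sequence[float]) -> tuple[float, float, float]:
    """Mean with Student-t 95% CI: mean ± t(0.975, n−1) · s/√n."""
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"CI needs n >= 2, got {n}")
    m = float(x.mean())
    half = float(stats.t.ppf(0.975, n - 1) * x.std(ddof=1) / np.sqrt(n))
    return m, m - half, m + half


def _all_parametric(groups: Sequence[np.ndarray]) -> bool:
    # groups too small for the normality check route to the robust branch
    if any(len(g) < 3 for g in groups):
        return False
    return all(is_parametric(g) for g in groups)


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    parametric: bool | None = None,
    mw_method: str = "asymptotic",
) -> StatReport:
    """Compare 2+ groups with the two-branch test dispatch.

    Parameters
    ----------
    groups
        Two or more samples, each with n >= 2.
    labels
        Optional group labels (defaults to g1, g2, ...).
    parametric
        Force the branch (True/False) instead of the Shapiro–Wilk dispatch;
        None (default) dispatches on the data.  Dispatch is deterministic —
        there is no randomness in the branch choice.
    mw_method
        p-value method for the Mann–Whitney U-test ("asymptotic", the
        tie-corrected normal approximation, or "exact").
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("need at least two groups")
    for g in arrays:
        if len(g) < 2:
            raise InsufficientDataError("every group needs n >= 2")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(arrays))]
    use_parametric = _all_parametric(arrays) if parametric is None else bool(parametric)

    if len(arrays) == 2:
        if use_parametric:
            res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
            test = "student_t"
        else:
            res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided", method=mw_method)
            test = "mann_whitney"
    else:
        if use_parametric:
            res = stats.f_oneway(*arrays)
            test = "anova"
        else:
            res = stats.kruskal(*arrays)
            test = "kruskal_wallis"

    summaries = tuple(
        GroupSummary(lab, len(g), *mean_ci95(g)) for lab, g in zip(labels, arrays)
    )
    return StatReport(
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=summaries,
    )
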