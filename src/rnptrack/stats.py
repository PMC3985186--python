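"""Condition summaries and two-group hypothesis tests.

Summaries report mean +/- SEM with n; group comparisons use the two
standard tests of this kind of motility work: the Mann-Whitney U test for
continuous metrics (run lengths, velocities, dwell times) and Fisher's
exact test for outcome proportions.  All tests are two-sided and star
annotations follow the conventional thresholds 0.05 / 0.01 / 0.001.  No
multiple-testing correction is applied by default (per-comparison
reporting); Holm adjustment is available for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ConditionSummary",
    "summarize_condition",
    "density_per_um",
    "compare_groups",
    "GroupComparison",
    "star_annotation",
    "holm_adjust",
]

STAR_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ConditionSummary:
    label: str
    mean: float
    sem: float
    n: int


def summarize_condition(values, label: str = "") -> ConditionSummary:
    """Mean +/- SEM summary of one metric under one condition."""
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        raise ValueError("need at least one record")
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return ConditionSummary(label=label, mean=float(arr.mean()), sem=sem, n=int(arr.size))


def density_per_um(count: int, mt_length_nm: float) -> float:
    """Particles (or puncta) per micrometre of microtubule."""
    if mt_length_nm <= 0:
        raise ValueError("microtubule length must be positive")
    return count / (mt_length_nm / 1000.0)


def star_annotation(p: float, thresholds: tuple[float, float, float] = STAR_THRESHOLDS) -> str:
    """'*', '**', '***' or 'ns' from a p-value."""
    if p < thresholds[2]:
        return "***"
    if p < thresholds[1]:
        return "**"
    if p < thresholds[0]:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    method: str  # exact vs asymptotic variant actually used


def compare_groups(a, b, test: str = "mann_whitney") -> GroupComparison:
    """Two-sided comparison of two groups.

    ``mann_whitney`` takes two sequences of values (exact null
    distribution for small tie-free samples, normal approximation with
    mid-rank tie correction otherwise, and the variant used is recorded);
    ``fisher_exact`` takes the two rows of a 2x2 contingency table.
    """
    if test == "mann_whitney":
        x = np.asarray(list(a), float)
        y = np.asarray(list(b), float)
        if x.size == 0 or y.size == 0:
            raise ValueError("groups must be non-empty")
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        exact = x.size <= 25 and y.size <= 25 and not has_ties
        method = "exact" if exact else "asymptotic"
        u, p = _stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return GroupComparison(
            test=test,
            statistic=float(u),
            p_value=float(p),
            stars=star_annotation(float(p)),
            n_a=int(x.size),
            n_b=int(y.size),
            method=method,
        )
    if test == "fisher_exact":
        table = np.asarray([list(a), list(b)], int)
        if table.shape != (2, 2):
            raise ValueError("fisher_exact expects the two rows of a 2x2 table")
        odds, p = _stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(
            test=test,
            statistic=float(odds),
            p_value=float(p),
            stars=star_annotation(float(p)),
            n_a=int(table[0].sum()),
            n_b=int(table[1].sum()),
            method="exact",
        )
    raise ValueError(f"unknown test {test!r}")


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(list(p_values), float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()
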