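"""Two-sample rank statistics shared by the expression and imaging pipelines.

Implements the Wilcoxon rank-sum (Mann-Whitney) test with an exact
small-sample mode, Bonferroni adjustment, and mean +/- SEM summaries.
These are deliberately self-contained so that every p-value reported by
the package carries explicit method metadata (exact vs. normal
approximation, tie handling, continuity correction).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RankSumResult", "rank_sum_test", "bonferroni", "mean_sem"]

# pooled-size cutoff below which the exact permutation distribution is
# enumerated (no ties only); C(12, 6) = 924 arrangements at worst
EXACT_MAX_POOLED = 12


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a two-sided Wilcoxon rank-sum test.

    ``statistic`` is W, the sum of pooled ranks of the first sample
    (midranks under ties). ``method`` records how the p-value was
    obtained: ``"exact"`` (full enumeration of the permutation
    distribution) or ``"normal-approximation"`` (tie-corrected variance,
    continuity correction).
    """

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    tie_correction: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their positions."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_two_sided_p(pooled_ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by doubling the smaller tail of the enumerated
    null distribution of W (capped at 1)."""
    n = len(pooled_ranks)
    w_values = [
        sum(pooled_ranks[i] for i in combo)
        for combo in itertools.combinations(range(n), n1)
    ]
    total = len(w_values)
    eps = 1e-9
    lower = sum(1 for w in w_values if w <= w_obs + eps)
    upper = sum(1 for w in w_values if w >= w_obs - eps)
    return min(1.0, 2.0 * min(lower, upper) / total)


def rank_sum_test(
    x,
    y,
    *,
    continuity: bool = True,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    The exact permutation distribution is enumerated when the pooled
    sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie-corrected variance (and, by default,
    a 0.5 continuity correction) is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires both samples to be non-empty")

    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n1 + n2 <= EXACT_MAX_POOLED and not has_ties:
        p = _exact_two_sided_p(ranks, n1, w)
        # enumeration can yield p == 0 only if the observed W is outside
        # the support, which cannot happen; still guard the open bound
        return RankSumResult(w, max(p, 1.0 / math.comb(n1 + n2, n1)), "exact", n1, n2, False)

    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all pooled values identical
        return RankSumResult(w, 1.0, "normal-approximation", n1, n2, has_ties)
    diff = w - mean_w
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var_w)
    p = min(1.0, float(math.erfc(abs(z) / math.sqrt(2.0))))
    return RankSumResult(w, max(p, np.nextafter(0.0, 1.0)), "normal-approximation", n1, n2, has_ties)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, p * m)``.

    ``m`` defaults to the number of p-values supplied; pass the size of
    the full test family when only a subset is being adjusted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0.0) or np.any(p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd / sqrt(n)).

    With fewer than two values the SEM is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("mean_sem requires at least one value")
    mean = float(v.mean())
    if v.size < 2:
        return mean, float("nan")
    sem = float(v.std(ddof=1) / math.sqrt(v.size))
    return mean, sem
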