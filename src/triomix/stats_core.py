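"""Exact small-sample Wilcoxon-Mann-Whitney rank test.

The exact null distribution of the Mann-Whitney U statistic is built by the
standard count recursion (equivalently, bounded-partition counting), giving
two-sided p-values as twice the lower-tail mass of the smaller orientation,
capped at 1.  Exact mode covers n1+n2 <= 20; ties switch to midrank scoring
with full enumeration over group assignments, and larger samples fall back
to the normal approximation with continuity and tie corrections.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

EXACT_LIMIT = 20


@dataclass(frozen=True)
class RankTestResult:
    """Result of a two-sample rank test.

    ``u_statistic`` is the smaller of the two orientations of
    U = #{(x_i, y_j): x_i < y_j} (ties counting 1/2).
    """

    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # 'exact', 'exact-ties' or 'normal'
    tied: bool = False


def null_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null probabilities of U over its support 0..n1*n2.

    Computed from the recursion counting arrangements of n1 x's among
    n1+n2 ranks with a given number of discordant pairs; symmetric about
    n1*n2/2 and summing to 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    if n1 + n2 > EXACT_LIMIT:
        raise ValidationError(f"exact mode requires n1+n2 <= {EXACT_LIMIT}")
    # arrangements with a given U biject with partitions of U into at most
    # n1 parts each <= n2 (the sorted counts of y's exceeding each x)
    total = math.comb(n1 + n2, n1)
    probs = np.array(
        [_partition_count(n1, n2, u) for u in range(n1 * n2 + 1)], dtype=float
    )
    return probs / total


@functools.lru_cache(maxsize=None)
def _partition_count(m: int, n: int, u: int) -> int:
    """Partitions of u into at most m parts, each at most n."""
    if u < 0:
        return 0
    if u == 0:
        return 1
    if m == 0 or n == 0:
        return 0
    # largest part < n, or remove one part equal to n
    return _partition_count(m, n - 1, u) + _partition_count(m - 1, n, u - n)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(x_i, y_j): x_i < y_j}, ties counting one half."""
    less = (x[:, None] < y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def exact_mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Exact two-sided Mann-Whitney test for small samples.

    Reports the smaller orientation of U and p = 2 * P(U <= observed) under
    the exact null (all C(n1+n2, n1) group assignments equally likely),
    capped at 1.  With ties the null is enumerated over assignments of the
    observed pooled values, scoring tied pairs 1/2; the result is flagged.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    u_xy = _u_statistic(x, y)
    u = min(u_xy, n1 * n2 - u_xy)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 + n2 > EXACT_LIMIT:
        p = _normal_p(x, y, u)
        return RankTestResult(u, p, n1, n2, "normal", has_ties)

    if not has_ties:
        probs = null_distribution(n1, n2)
        p = min(1.0, 2.0 * float(probs[: int(u) + 1].sum()))
        return RankTestResult(u, p, n1, n2, "exact", False)

    # ties: enumerate all group assignments of the observed pooled values
    idx = range(n1 + n2)
    tail = 0
    total = 0
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(combo)] = True
        u_perm = _u_statistic(pooled[mask], pooled[~mask])
        u_perm = min(u_perm, n1 * n2 - u_perm)
        if u_perm <= u + 1e-9:
            tail += 1
        total += 1
    p = min(1.0, 2.0 * tail / total)
    return RankTestResult(u, p, n1, n2, "exact-ties", True)


def _normal_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Normal approximation with continuity correction and tie-corrected variance."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (u - mu + 0.5) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.cdf(z))
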