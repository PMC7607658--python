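"""Group-comparison statistics: paired signed-rank, rank-sum and normality.

The rank tests use exact null distributions (by generating-function
convolution over midranks) for small samples and the normal approximation
with continuity and tie corrections otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from methdrift.errors import DomainError

EXACT_LIMIT_SIGNED_RANK = 12  # pairs
EXACT_LIMIT_RANK_SUM = 12  # combined sample size


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    n: int
    n_zero_dropped: int = 0


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_exact_p(ranks2: np.ndarray, w2: int, alternative: str) -> float:
    """Exact tail probability of W (doubled ranks, integer arithmetic)."""
    dist: dict[int, int] = {0: 1}
    for r in ranks2:
        new: dict[int, int] = {}
        for s, cnt in dist.items():
            new[s] = new.get(s, 0) + cnt
            new[s + int(r)] = new.get(s + int(r), 0) + cnt
        dist = new
    total = 2 ** len(ranks2)
    sum2 = int(ranks2.sum())
    if alternative == "greater":
        hits = sum(cnt for s, cnt in dist.items() if s >= w2)
    elif alternative == "less":
        hits = sum(cnt for s, cnt in dist.items() if s <= w2)
    else:
        dev = abs(2 * w2 - sum2)
        hits = sum(cnt for s, cnt in dist.items() if abs(2 * s - sum2) >= dev)
    return min(1.0, hits / total)


def paired_signed_rank(
    values_t1, values_t2, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test on paired vectors (t2 - t1 differences).

    Zero differences are dropped and counted; exact enumeration for <= 12
    remaining pairs, else normal approximation with continuity correction.
    """
    x1 = np.asarray(values_t1, dtype=float)
    x2 = np.asarray(values_t2, dtype=float)
    if x1.shape != x2.shape:
        raise DomainError("paired vectors must have equal length")
    d = x2 - x1
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        raise DomainError("all paired differences are zero: test undefined")
    ranks = _midranks(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT_SIGNED_RANK:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        p = _signed_rank_exact_p(ranks2, w2, alternative)
        method = "exact"
    else:
        mu = ranks.sum() / 2.0
        # tie-aware variance of W+ over random signs
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        if alternative == "greater":
            z = (w - mu - 0.5) / sigma
            p = sps.norm.sf(z)
        elif alternative == "less":
            z = (w - mu + 0.5) / sigma
            p = sps.norm.cdf(z)
        else:
            z = (abs(w - mu) - 0.5) / sigma
            p = 2.0 * sps.norm.sf(z)
        p = float(min(1.0, max(0.0, p)))
        method = "normal-approx"
    return TestResult(statistic=w, p=float(p), method=method, n=n, n_zero_dropped=n_zero)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _rank_sum_exact_p(
    ranks2: np.ndarray, n_a: int, w2: int, alternative: str
) -> float:
    """Exact tail of the rank sum of group A over all subset assignments."""
    from math import comb

    dist: dict[tuple[int, int], int] = {(0, 0): 1}
    for r in ranks2:
        new: dict[tuple[int, int], int] = {}
        for (k, s), cnt in dist.items():
            new[(k, s)] = new.get((k, s), 0) + cnt
            if k < n_a:
                key = (k + 1, s + int(r))
                new[key] = new.get(key, 0) + cnt
        dist = new
    n = len(ranks2)
    total = comb(n, n_a)
    sums = {s: cnt for (k, s), cnt in dist.items() if k == n_a}
    sum2 = int(ranks2.sum())
    if alternative == "greater":
        hits = sum(cnt for s, cnt in sums.items() if s >= w2)
    elif alternative == "less":
        hits = sum(cnt for s, cnt in sums.items() if s <= w2)
    else:
        dev = abs(n * w2 - n_a * sum2)
        hits = sum(cnt for s, cnt in sums.items() if abs(n * s - n_a * sum2) >= dev)
    return min(1.0, hits / total)


def rank_sum(group_a, group_b, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum test with midrank ties.

    Exact for combined sample size <= 12, else normal approximation with
    tie and continuity corrections. Statistic is the rank sum of group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DomainError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    n, n_a = len(combined), len(a)
    ranks = _midranks(combined)
    w = float(ranks[:n_a].sum())
    if n <= EXACT_LIMIT_RANK_SUM:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        p = _rank_sum_exact_p(ranks2, n_a, w2, alternative)
        method = "exact"
    else:
        n_b = n - n_a
        mu = n_a * (n + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
        sigma = np.sqrt(n_a * n_b / 12.0 * (n + 1 - tie_term))
        if sigma == 0:
            raise DomainError("all observations tied: rank-sum variance is zero")
        if alternative == "greater":
            p = sps.norm.sf((w - mu - 0.5) / sigma)
        elif alternative == "less":
            p = sps.norm.cdf((w - mu + 0.5) / sigma)
        else:
            p = 2.0 * sps.norm.sf((abs(w - mu) - 0.5) / sigma)
        p = float(min(1.0, max(0.0, p)))
        method = "normal-approx"
    return TestResult(statistic=w, p=float(p), method=method, n=n)


def normality_check(values) -> TestResult:
    """Shapiro-Wilk normality test (delegated to a vetted routine)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DomainError("normality check needs at least 3 values")
    stat, p = sps.shapiro(x)
    return TestResult(statistic=float(stat), p=float(p), method="shapiro-wilk", n=len(x))
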