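"""Rank statistics: two-tailed Mann-Whitney U and Benjamini-Hochberg FDR.

The U statistic counts pairs where x exceeds y, with half-credit for ties:
``U = #{(i,j): x_i > y_j} + 0.5 * #ties``. Exact two-tailed p-values are
``2 * min(P(U <= u), P(U >= u))`` capped at 1, computed by full enumeration
of group assignments; without ties the null distribution of U comes from the
standard counting recurrence, which is cheap for any n1*n2 <= 400. Larger
samples use the normal approximation with tie correction and a continuity
correction of 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm

__all__ = ["TestResult", "mann_whitney_u", "bh_fdr", "star_code"]

_ENUM_LIMIT = 200_000  # max C(n1+n2, n1) for brute-force enumeration with ties


@dataclass
class TestResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str
    q: float | None = None

    @property
    def stars(self) -> str:
        return star_code(self.p if self.q is None else self.q)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value, for tie-free samples."""
    if m == 0 or n == 0:
        return (1,)
    a = _u_counts(m - 1, n)  # last pooled value belongs to x: adds n to U
    b = _u_counts(m, n - 1)  # ... belongs to y: adds nothing
    out = [0] * (m * n + 1)
    for u, c in enumerate(a):
        out[u + n] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _two_tailed(p_le: float, p_ge: float) -> float:
    return min(1.0, 2.0 * min(p_le, p_ge))


def _exact_p_tiefree(u: float, n1: int, n2: int) -> float:
    counts = np.asarray(_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    k = int(round(u))
    return _two_tailed(counts[: k + 1].sum() / total, counts[k:].sum() / total)


def _exact_p_enumerate(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    le = ge = total = 0
    for idx in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        le += u <= u_obs + 1e-12
        ge += u >= u_obs - 1e-12
        total += 1
    return _two_tailed(le / total, ge / total)


def _approx_p(u: float, x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, t = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    return min(1.0, 2.0 * norm.sf(abs(z)))


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-tailed Mann-Whitney U test.

    ``mode`` is ``exact`` (enumeration; counting recurrence when tie-free),
    ``normal_approx``, or ``auto`` (exact when ``n1*n2 <= 400`` and
    enumeration is feasible, else the approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one observation")
    u = _u_statistic(x, y)
    has_ties = np.intersect1d(x, y).size > 0 or np.unique(x).size < x.size or np.unique(y).size < y.size
    n1, n2 = x.size, y.size

    def exact_feasible() -> bool:
        return (not has_ties) or comb(n1 + n2, n1) <= _ENUM_LIMIT

    if mode == "auto":
        mode = "exact" if (n1 * n2 <= 400 and exact_feasible()) else "normal_approx"
    if mode == "exact":
        if not has_ties:
            p = _exact_p_tiefree(u, n1, n2)
        elif comb(n1 + n2, n1) <= _ENUM_LIMIT:
            p = _exact_p_enumerate(x, y, u)
        else:
            raise ValueError("exact mode infeasible for tied samples of this size")
        method = "exact"
    elif mode == "normal_approx":
        p = _approx_p(u, x, y)
        method = "normal_approx"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(u=u, p=p, n1=n1, n2=n2, method=method)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def star_code(q: float) -> str:
    """Significance stars with inclusive thresholds: ***<=0.001, **<=0.01, *<=0.05."""
    if not 0 <= q <= 1:
        raise ValueError("adjusted p-value outside [0, 1]")
    if q <= 0.001:
        return "***"
    if q <= 0.01:
        return "**"
    if q <= 0.05:
        return "*"
    return "ns"
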