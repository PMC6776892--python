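"""Shared statistical primitives.

The broad-mark island caller and the differential-binding test both rest on
upper tails of the Poisson distribution at extreme quantiles (the pipeline
thresholds p at 1e-20 and islands routinely reach p < 1e-300), so the tail is
computed in log space and stays finite far below the smallest double.  The
enrichment tests (Fisher two-tailed, hypergeometric) are computed with exact
integer arithmetic so that knife-edge tables are resolved without floating
point ties.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import special

__all__ = [
    "log_poisson_sf",
    "poisson_sf",
    "bh_adjust",
    "holm_adjust",
    "fisher_exact_two_tailed",
    "hypergeom_upper_tail",
]

_LN10 = math.log(10.0)


def log_poisson_sf(k, lam):
    """Natural log of the Poisson upper tail ``P(X >= k)`` with mean ``lam``.

    Exact to ~1e-13 relative error in the log, down to (and far below)
    p = 1e-300.  For ``k <= lam`` the regularized lower incomplete gamma is
    used directly (the tail is then of order one); for ``k > lam`` the tail is
    summed as ``pmf(k) * (1 + lam/(k+1) + lam^2/((k+1)(k+2)) + ...)``, a
    series with geometrically decreasing terms, and assembled in log space.

    Parameters
    ----------
    k : int or array-like
        Threshold count(s); ``P(X >= k)``.  Values ``<= 0`` give log(1) = 0.
    lam : float or array-like
        Poisson mean(s), ``> 0``.

    Returns
    -------
    float or ndarray of the natural-log tail probability.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=float))
    lam_arr = np.broadcast_to(np.atleast_1d(np.asarray(lam, dtype=float)), k_arr.shape).copy()
    if np.any(lam_arr <= 0):
        raise ValueError("Poisson mean must be positive")
    out = np.empty(k_arr.shape, dtype=float)
    for i, (kk, ll) in enumerate(zip(k_arr.ravel(), lam_arr.ravel())):
        out.ravel()[i] = _log_poisson_sf_scalar(int(math.ceil(kk)), float(ll))
    if np.isscalar(k) or (np.ndim(k) == 0 and np.ndim(lam) == 0):
        return float(out.ravel()[0])
    return out


def _log_poisson_sf_scalar(k: int, lam: float) -> float:
    if k <= 0:
        return 0.0
    if k <= lam:
        # bulk: P(X >= k) = 1 - P(X <= k-1); the complement P(X <= k-1) =
        # gammaincc(k, lam) is <= ~1/2 here, so log1p keeps full precision
        # even when the tail is within 1e-300 of one.
        return math.log1p(-special.gammaincc(k, lam))
    # log pmf at k
    log_pmf = k * math.log(lam) - lam - math.lgamma(k + 1)
    # tail ratio series: t_0 = 1, t_j = t_{j-1} * lam / (k + j)
    s = 1.0
    t = 1.0
    j = 1
    while True:
        t *= lam / (k + j)
        s += t
        if t < s * 1e-18:
            break
        j += 1
    return log_pmf + math.log(s)


def poisson_sf(k, lam):
    """Poisson upper tail ``P(X >= k)`` in linear space (may underflow to 0)."""
    return np.exp(log_poisson_sf(k, lam))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_i = min_{j: p_j >= p_i} (p_j * n / rank_j)`` clipped to 1; monotone
    non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values.

    ``adj_(i) = max_{j <= i} min(1, (n - j + 1) * p_(j))`` over the ascending
    order statistics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    mult = (n - np.arange(n)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(mult), 1.0)
    adj = np.empty(n, dtype=float)
    adj[order] = adj_sorted
    return adj


def _hypergeom_pmf_fraction(a: int, row1: int, row2: int, col1: int) -> Fraction:
    """Exact P(table with top-left = a) for fixed margins, as a Fraction."""
    n = row1 + row2
    return Fraction(math.comb(row1, a) * math.comb(row2, col1 - a), math.comb(n, col1))


def fisher_exact_two_tailed(table) -> tuple[float, float]:
    """Two-tailed Fisher's exact test by the point-probability rule.

    The two-sided p-value is the sum, over all 2x2 tables with the observed
    margins, of probabilities no larger than the observed table's probability.
    Computed with exact rational arithmetic, so ties at the observed
    probability are resolved exactly rather than to floating-point tolerance.

    Parameters
    ----------
    table : 2x2 array-like of non-negative ints ``[[a, b], [c, d]]``.

    Returns
    -------
    (odds_ratio, p_value).  Odds ratio is ``(a*d)/(b*c)``; ``nan`` when the
    ratio is 0/0 (undefined), ``inf`` when only the denominator is zero.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    num, den = a * d, b * c
    if num == 0 and den == 0:
        odds = float("nan")
    elif den == 0:
        odds = float("inf")
    else:
        odds = num / den
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = _hypergeom_pmf_fraction(a, row1, row2, col1)
    p_total = Fraction(0)
    for x in range(lo, hi + 1):
        px = _hypergeom_pmf_fraction(x, row1, row2, col1)
        if px <= p_obs:
            p_total += px
    return odds, float(min(p_total, Fraction(1)))


def hypergeom_upper_tail(overlap: int, n_hits: int, n_set: int, n_universe: int) -> float:
    """Upper-tail hypergeometric p of observing >= ``overlap`` shared genes.

    Drawing ``n_hits`` genes without replacement from a universe of
    ``n_universe`` containing ``n_set`` marked genes; exact rational sum.
    """
    if not (0 <= n_hits <= n_universe and 0 <= n_set <= n_universe):
        raise ValueError("set sizes must be within the universe")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    hi = min(n_hits, n_set)
    p = Fraction(0)
    denom = math.comb(n_universe, n_hits)
    for x in range(overlap, hi + 1):
        p += Fraction(math.comb(n_set, x) * math.comb(n_universe - n_set, n_hits - x), denom)
    return float(min(p, Fraction(1)))
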