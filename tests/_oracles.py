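"""Independent brute-force / high-precision oracles shared by the
acceptance-level tests.  Each oracle re-derives its quantity from the
definition, never through the package's own code paths."""

import math
from fractions import Fraction

import mpmath

mpmath.mp.dps = 400


def mp_log10_poisson_sf(k: int, lam) -> float:
    """Arbitrary-precision log10 of the Poisson upper tail P(X >= k)."""
    lam = mpmath.mpf(lam)
    if k <= 0:
        return 0.0
    if k <= lam:
        lower = sum(mpmath.e ** (-lam) * lam ** j / mpmath.factorial(j)
                    for j in range(k))
        return float(mpmath.log10(1 - lower))
    term = mpmath.e ** (-lam) * lam ** k / mpmath.factorial(k)
    total, j = term, k
    while True:
        j += 1
        term = term * lam / j
        total += term
        if term < total * mpmath.mpf("1e-60") and j > lam:
            break
    return float(mpmath.log10(total))


def fisher_two_tailed_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-tailed p by exhaustive fixed-margin enumeration,
    with pmfs in the factorial form, all in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x: int) -> Fraction:
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return Fraction(0)
        return Fraction(
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(n - c1),
            math.factorial(n) * math.factorial(x) * math.factorial(y)
            * math.factorial(z) * math.factorial(w))

    p_obs = pmf(a)
    total = sum(p for x in range(min(r1, c1) + 1) if (p := pmf(x)) <= p_obs)
    return float(min(total, Fraction(1)))


def hypergeom_tail_enumeration(overlap: int, n_hits: int, n_set: int,
                               n_universe: int) -> float:
    total = Fraction(0)
    for x in range(overlap, min(n_hits, n_set) + 1):
        total += Fraction(math.comb(n_set, x)
                          * math.comb(n_universe - n_set, n_hits - x),
                          math.comb(n_universe, n_hits))
    return float(min(total, Fraction(1)))


def bh_step_up(p: list[float]) -> list[float]:
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    rank = {i: r for r, i in enumerate(order, 1)}
    return [min(min(1.0, p[j] * n / rank[j]) for j in range(n) if p[j] >= p[i])
            for i in range(n)]


def holm_step_down(p: list[float]) -> list[float]:
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj, running = {}, 0.0
    for r, i in enumerate(order):
        running = max(running, min(1.0, (n - r) * p[i]))
        adj[i] = running
    return [adj[i] for i in range(n)]


def enumerate_islands(counts, window_bp, gap_bp, eligibility_p, island_fdr,
                      library_size, genome_length, egf=0.75):
    """Exhaustive eligible-run enumeration for micro window fixtures."""
    lam = library_size * window_bp / (genome_length * egf)
    c0 = 1
    while 10 ** mp_log10_poisson_sf(c0, lam) > eligibility_p:
        c0 += 1
    eligible = [i for i, c in enumerate(counts) if c >= c0]
    runs = []
    for i in eligible:
        if runs and (i - runs[-1][-1] - 1) * window_bp <= gap_bp:
            runs[-1].append(i)
        else:
            runs.append([i])
    cands = []
    for run in runs:
        first, last = run[0], run[-1]
        total = sum(counts[first:last + 1])
        p = 10 ** mp_log10_poisson_sf(total, lam * (last - first + 1))
        cands.append((first * window_bp, (last + 1) * window_bp, total, min(p, 1.0)))
    if not cands:
        return []
    qs = bh_step_up([c[3] for c in cands])
    return sorted((s, e, t) for (s, e, t, _), q in zip(cands, qs) if q < island_fdr)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))
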