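"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths (and numpy vector
tricks): plain Python lists, math functions, exhaustive enumeration.
"""

from __future__ import annotations

import math


def oracle_midranks(values: list[float]) -> list[float]:
    """1-based ranks, ties averaged, by explicit pairwise comparison."""
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        # ranks occupied by the tie group: less+1 .. less+equal
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def oracle_tmm_log2_factor(
    yk: list[int],
    yr: list[int],
    nk: float,
    nr: float,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    a_min: float | None = None,
    weighted: bool = True,
) -> float:
    """Straight-line recomputation of the doubly trimmed weighted mean of M."""
    m_vals, a_vals, weights = [], [], []
    for a, b in zip(yk, yr):
        if a <= 0 or b <= 0:
            continue
        var = (nk - a) / (nk * a) + (nr - b) / (nr * b)
        if var == 0:
            continue
        num, den = a * nr, b * nk
        m = math.log2(num / den) if num >= den else -math.log2(den / num)
        aa = 0.5 * math.log2((a * b) / (nk * nr))
        if a_min is not None and aa < a_min:
            continue
        m_vals.append(m)
        a_vals.append(aa)
        weights.append(1.0 / var)
    n = len(m_vals)
    if n == 0:
        raise ValueError("no valid genes")
    lo_m, hi_m = math.floor(n * m_trim) + 1, n - math.floor(n * m_trim)
    lo_a, hi_a = math.floor(n * a_trim) + 1, n - math.floor(n * a_trim)
    rank_m = oracle_midranks(m_vals)
    rank_a = oracle_midranks(a_vals)
    num = den = 0.0
    kept = 0
    for i in range(n):
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
            kept += 1
            if weighted:
                num += weights[i] * m_vals[i]
                den += weights[i]
            else:
                num += m_vals[i]
                den += 1.0
    if kept == 0:
        raise ValueError("all genes trimmed")
    return num / den


def oracle_exact_binomial_p(y1: int, y2: int, n1: float, n2: float) -> float:
    """Exhaustive conditional-binomial two-sided p (math.comb, no scipy)."""
    t = y1 + y2
    if t == 0:
        return 1.0
    p = n1 / (n1 + n2)
    pmf = [math.comb(t, x) * p**x * (1 - p) ** (t - x) for x in range(t + 1)]
    observed = pmf[y1]
    total = sum(q for q in pmf if q <= observed * (1 + 1e-7))
    return min(total, 1.0)
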