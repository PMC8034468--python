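"""Independent brute-force oracles used to freeze expected values.

Everything here is computed by exhaustive enumeration or direct hand-style
arithmetic (exact rational arithmetic where possible) and is deliberately
independent of the implementation paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_reversal_p(n_ref: int, k_ref_less: int, n_other: int, k_other_less: int) -> Fraction:
    """Exact tail P(X >= k_other_less) for X ~ Hypergeom(N, K, n_other).

    N pools both groups' evaluable samples, K is the total reversal count,
    and X counts reversals landing in the other group.
    """
    total = n_ref + n_other
    reversals = k_ref_less + k_other_less
    if total == 0:
        return Fraction(1)
    denom = comb(total, n_other)
    tail = Fraction(0)
    for x in range(k_other_less, min(reversals, n_other) + 1):
        if reversals - x > total - n_other:
            continue
        tail += Fraction(comb(reversals, x) * comb(total - reversals, n_other - x), denom)
    return tail


def binom_tail(k: int, n: int) -> Fraction:
    """Exact P(X >= k) for X ~ Binomial(n, 1/2)."""
    return Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by table enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's (with a tiny relative
    slack against floating-point ties, as is conventional).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, row1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(col1, x) * comb(n - col1, row1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs or abs(float(px) - float(p_obs)) < 1e-12 * float(p_obs):
            total += px
    return float(min(total, Fraction(1)))


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written independently (sort + cummin)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        q[i] = running_min
    return q


def km_product_limit(times: list[float], events: list[int]) -> list[tuple[float, float]]:
    """Hand product-limit estimator: (event time, survival) pairs."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    survival = 1.0
    out = []
    at_risk = len(times)
    i = 0
    while i < len(order):
        t = times[order[i]]
        deaths = sum(
            1 for j in order[i:] if times[j] == t and events[j] == 1
        )
        removed = sum(1 for j in order[i:] if times[j] == t)
        if deaths > 0:
            survival *= 1 - deaths / at_risk
            out.append((t, survival))
        at_risk -= removed
        i += removed
    return out


def logrank_chi2(
    times_a: list[float], events_a: list[int], times_b: list[float], events_b: list[int]
) -> float:
    """Hand two-group log-rank statistic (O - E)^2 / V over pooled event times."""
    pooled = sorted(
        {t for t, e in zip(times_a + times_b, events_a + events_b) if e == 1}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in pooled:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return o_minus_e**2 / var if var > 0 else 0.0
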