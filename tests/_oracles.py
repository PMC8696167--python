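"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pure-Python loops, explicit
combinatorial sums) and shares no code with the package.
"""

from __future__ import annotations

import math


def brute_force_es(r: list[float], hit: list[bool]) -> tuple[float, int]:
    """Enrichment score by walking every prefix explicitly.

    ``r`` is the rank metric in list order (already sorted descending),
    ``hit`` flags set membership per position.  Returns (ES, position of
    the maximum absolute deviation, first on ties).
    """
    n = len(r)
    n_h = sum(hit)
    n_r = sum(abs(x) for x, h in zip(r, hit) if h)
    if n_r == 0:
        raise ValueError("degenerate set")
    best_dev, best_pos = 0.0, 0
    p_hit = p_miss = 0.0
    for i in range(n):
        if hit[i]:
            p_hit += abs(r[i]) / n_r
        else:
            p_miss += 1.0 / (n - n_h)
        dev = p_hit - p_miss
        if abs(dev) > abs(best_dev) + 1e-15:
            best_dev, best_pos = dev, i
    return best_dev, best_pos


def binom_pmf(k: int, n: int, p: float = 0.5) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def exact_symmetry_pvalue(a: int, n: int) -> float:
    """Exact two-sided p-value for a single discordant pair (a of n).

    The symmetry statistic for one discordant pair is ``(2X - n)^2 / n``
    with ``X ~ Binomial(n, 1/2)`` under the null, so the p-value is
    ``P(|2X - n| >= |2a - n|)`` -- an explicit binomial sum.
    """
    target = abs(2 * a - n)
    return sum(binom_pmf(k, n) for k in range(n + 1) if abs(2 * k - n) >= target)


def hypergeom_upper_tail(x: int, universe: int, draws: int, successes: int) -> float:
    """P(overlap >= x) by explicit combinatorial summation.

    ``draws`` is the set size, ``successes`` the number of significant
    genes in the universe.
    """
    total = math.comb(universe, successes)
    acc = 0.0
    for k in range(x, min(draws, successes) + 1):
        acc += math.comb(draws, k) * math.comb(universe - draws, successes - k) / total
    return acc


def fisher_combined_df4(p1: float, p2: float) -> float:
    """Closed-form Fisher combination for exactly two p-values.

    For chi-square with 4 df the survival function at F is
    ``exp(-F/2) * (1 + F/2)``.
    """
    f = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-f / 2) * (1 + f / 2)
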