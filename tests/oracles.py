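"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a statistic from first principles (enumeration or
the textbook definition) without touching the implementation under test.
"""

from __future__ import annotations

import math


def pathotype_truth_table(cd3, cd20, cd68l, cd68sl, cd138, agg) -> str:
    """Printed pathotype criteria, evaluated as independent predicates
    resolved by precedence L > M > F."""
    rule_l = (agg in (2, 3) and cd20 >= 2) or cd138 > 2
    rule_m = cd68sl >= 2 and cd138 <= 2 and (cd20 <= 1 or cd3 >= 1)
    rule_f = cd68sl < 2 and cd3 < 1 and cd20 < 1 and cd138 < 1
    if rule_l:
        return "lymphoid"
    if rule_m:
        return "myeloid"
    if rule_f:
        return "fibroid"
    return "ungraded"


def bh_oracle(pvals: list[float]) -> list[float]:
    """Textbook step-up BH: q_i = min_{p_j >= p_i} (m * p_j / rank_j)."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = min(running, 1.0)
    return q


def hypergeom_tail_oracle(k: int, pop: int, successes: int, draws: int) -> float:
    """P(X >= k) by exact combinatorial summation."""
    denom = math.comb(pop, draws)
    total = 0
    for i in range(k, min(successes, draws) + 1):
        total += math.comb(successes, i) * math.comb(pop - successes, draws - i)
    return total / denom


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing those no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(top-left cell = x) under fixed margins
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
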