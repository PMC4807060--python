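"""Independent brute-force references used as oracles by the tests.

Everything here is written as plain double loops straight from the defining
formulas, deliberately sharing no code with the package implementation.
"""

import itertools
import math


def brute_cross_sample_entropy(u, v, m, r):
    """Heaviside cross entropy by explicit double loop; None when undefined."""
    N = len(u)

    def match_fraction(order):
        count = 0
        total = 0
        for i in range(N - m):          # N - m templates at BOTH orders
            for j in range(N - m):
                d = max(abs(u[i + k] - v[j + k]) for k in range(order))
                total += 1
                if d < r:
                    count += 1
        return count / total

    b_m = match_fraction(m)
    b_m1 = match_fraction(m + 1)
    if b_m == 0 or b_m1 == 0:
        return None
    return -math.log(b_m1 / b_m)


def brute_cross_fuzzy_entropy(u, v, m, n, r):
    """Fuzzy cross entropy with per-window baseline removal, double loop."""
    N = len(u)

    def centered(series, start, order):
        window = [series[start + k] for k in range(order)]
        mean = sum(window) / order
        return [w - mean for w in window]

    def phi(order):
        total = 0.0
        for i in range(N - m):
            x = centered(u, i, order)
            for j in range(N - m):
                y = centered(v, j, order)
                d = max(abs(a - b) for a, b in zip(x, y))
                total += math.exp(-(d**n) / r)
        return total / (N - m) ** 2

    return -math.log(phi(m + 1) / phi(m))


def exact_mannwhitney_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Only valid without ties across groups.  The statistic enumerated is the
    count of (a, b) pairs with a > b; two-sided p doubles the smaller tail
    (capped at 1), matching the standard exact test.
    """
    na, nb = len(a), len(b)
    observed = sum(1 for x in a for y in b if x > y)
    pooled = list(a) + list(b)
    stats = []
    for comb in itertools.combinations(range(na + nb), na):
        grp_a = [pooled[i] for i in comb]
        grp_b = [pooled[i] for i in range(na + nb) if i not in comb]
        stats.append(sum(1 for x in grp_a for y in grp_b if x > y))
    n_total = len(stats)
    lo = sum(1 for s in stats if s <= observed) / n_total
    hi = sum(1 for s in stats if s >= observed) / n_total
    return min(1.0, 2.0 * min(lo, hi))


def brute_auc(scores, labels, positive):
    """ROC area by counting concordant positive-negative pairs (ties half)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
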