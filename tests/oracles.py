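"""Independent brute-force oracles, written with plain Python loops.

These deliberately avoid the vectorised implementation paths so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations


def brute_smooth(values, span=0.05):
    """Shrinking-window centered moving average, loop implementation."""
    v = list(map(float, values))
    n = len(v)
    if n < 3:
        return v[:]
    w = max(3, round(span * n))
    if w % 2 == 0:
        w += 1
    h = w // 2
    out = []
    for k in range(n):
        lo, hi = max(0, k - h), min(n - 1, k + h)
        out.append(sum(v[lo : hi + 1]) / (hi - lo + 1))
    return out


def brute_cumsum(od, lengths):
    total = 0.0
    out = []
    for o, l in zip(od, lengths):
        total += o / l
        out.append(total)
    return out


def brute_invert(C, L, target):
    """Linear-search inversion of the cumulative curve at ``target``."""
    for i, c in enumerate(C):
        if c > target:
            if i == 0:
                L0 = 2 * L[0] - L[1]
                return L0 + (L[0] - L0) * target / C[0] if C[0] > 0 else L[0]
            return L[i - 1] + (L[i] - L[i - 1]) * (target - C[i - 1]) / (C[i] - C[i - 1])
    return L[-1]


def brute_weighted_stats(od, lengths):
    """(median, q1, q3) by full cumulative construction and linear search."""
    C = brute_cumsum(od, lengths)
    total = C[-1]
    med = brute_invert(C, list(lengths), total / 2)
    qa = brute_invert(C, list(lengths), total / 4)
    qb = brute_invert(C, list(lengths), 3 * total / 4)
    return med, min(qa, qb), max(qa, qb)


def brute_welch(a, b):
    """Closed-form Welch statistic, df and two-tailed p."""
    import math

    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df, 2 * tdist.sf(abs(t), df)
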