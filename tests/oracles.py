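"""Independent brute-force oracles used only by the tests.

Deliberately naive (pure-Python loops, direct enumeration) so they share no
code path with the package implementation they check.
"""
from __future__ import annotations

import itertools
import math


def naive_time_domain(rr: list[float]) -> dict[str, float]:
    """Direct reimplementation of the ten time-domain HRV measures."""
    n = len(rr)
    mean = sum(rr) / n

    def median(xs):
        ys = sorted(xs)
        m = len(ys)
        return ys[m // 2] if m % 2 else (ys[m // 2 - 1] + ys[m // 2]) / 2.0

    med = median(rr)
    mad = median([abs(x - med) for x in rr]) * 1.4826
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in rr) / (n - 1))
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(x * x for x in d) / len(d))
    dmean = sum(d) / len(d)
    sdsd = math.sqrt(sum((x - dmean) ** 2 for x in d) / (len(d) - 1))

    def percentile(xs, q):
        ys = sorted(xs)
        pos = (len(ys) - 1) * q / 100.0
        lo = int(math.floor(pos))
        hi = min(lo + 1, len(ys) - 1)
        return ys[lo] + (ys[hi] - ys[lo]) * (pos - lo)

    return {
        "MeanNN": mean, "MedianNN": med, "MadNN": mad, "SDNN": sdnn,
        "RMSSD": rmssd, "SDSD": sdsd,
        "Prc80NN": percentile(rr, 80), "Prc20NN": percentile(rr, 20),
        "pNN20": 100.0 * sum(1 for x in d if abs(x) > 20) / len(d),
        "pNN50": 100.0 * sum(1 for x in d if abs(x) > 50) / len(d),
    }


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def exact_signed_rank_p(d: list[float]) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = [x for x in d if x != 0]
    n = len(d)
    ranks = _midranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ge = le = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if w >= w_obs - 1e-12:
            ge += 1
        if w <= w_obs + 1e-12:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def exact_rank_sum_p(a: list[float], b: list[float]) -> float:
    """Two-sided rank-sum p by enumerating all assignments of the pooled
    sample to group A (requires a tie-free pooled sample)."""
    pooled = list(a) + list(b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = _midranks(pooled)
    n1 = len(a)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    ge = le = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)
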