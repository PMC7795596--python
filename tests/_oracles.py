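"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the textbook definitions, in plain
Python loops, sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def gsea_es_oracle(genes, scores, gene_set, weight_exponent=1.0):
    """Enrichment score by walking the full running sum, one gene at a time.

    Hits add |score|^p / (total hit weight); misses subtract 1/(N - Nh).
    ES is the walk value of largest magnitude (ties resolve positive).
    """
    hits = [g in gene_set for g in genes]
    n = len(genes)
    nh = sum(hits)
    assert 0 < nh < n
    total = sum(abs(s) ** weight_exponent for s, h in zip(scores, hits) if h)
    walk, value = [], 0.0
    for s, h in zip(scores, hits):
        if h:
            value += (abs(s) ** weight_exponent / total) if total > 0 else 1.0 / nh
        else:
            value -= 1.0 / (n - nh)
        walk.append(value)
    hi, lo = max(walk), min(walk)
    return hi if hi >= -lo else lo


def km_oracle(times, events, query_time):
    """Product-limit estimate S(query_time), censorings after events at ties."""
    times = list(map(float, times))
    events = list(map(int, events))
    event_times = sorted({t for t, e in zip(times, events) if e == 1 and t <= query_time})
    s = 1.0
    for t in event_times:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - d / at_risk
    return s


def logrank_oracle(times, events, groups):
    """k-group log-rank chi-square from the per-event-time hypergeometric table."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        d = int(((times == t) & (events == 1)).sum())
        ng = np.array([(at_risk & (groups == lab)).sum() for lab in labels], float)
        dg = np.array(
            [((times == t) & (events == 1) & (groups == lab)).sum() for lab in labels], float
        )
        observed += dg
        expected += ng * d / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for i in range(k):
                for j in range(k):
                    if i == j:
                        var[i, j] += factor * ng[i] / n * (1 - ng[i] / n)
                    else:
                        var[i, j] -= factor * ng[i] * ng[j] / n**2
    z = (observed - expected)[: k - 1]
    v = var[: k - 1, : k - 1]
    chi2 = float(z @ np.linalg.solve(v, z))
    return chi2, k - 1, float(stats.chi2.sf(chi2, k - 1))


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all C(n1+n2, n1) labelings."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free data"
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    us = [
        u_stat(combo, [v for v in pooled if v not in combo])
        for combo in itertools.combinations(pooled, n1)
    ]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_oracle(p_values):
    """Benjamini-Hochberg by the step-up definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def spearman_oracle(x, y):
    """Pearson correlation of mid-ranks, from the definition."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            for t in range(i, j + 1):
                ranks[order[t]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
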