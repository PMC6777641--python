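"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: ranks are computed by
counting comparisons, the Kruskal-Wallis statistic uses the rank
sum-of-squares identity H = (N-1) * SSB / SST (equivalent to the
tie-corrected classical form), and the Trouvelot indices are accumulated
per fragment rather than per class tally.
"""

from __future__ import annotations

import math
from itertools import combinations

_MYC_WEIGHT = {0: 0.0, 1: 1.0, 2: 5.0, 3: 30.0, 4: 70.0, 5: 95.0}
_ARB_FACTOR = {0: 0.0, 1: 0.1, 2: 0.5, 3: 1.0}


def counting_ranks(values):
    """Midranks by counting: rank = #smaller + (#equal + 1)/2."""
    return [sum(1 for u in values if u < v)
            + (sum(1 for u in values if u == v) + 1) / 2.0
            for v in values]


def kw_statistic(groups):
    """Tie-corrected Kruskal-Wallis H via the rank variance-ratio identity."""
    pooled = [float(v) for g in groups for v in g]
    N = len(pooled)
    ranks = counting_ranks(pooled)
    grand = sum(ranks) / N
    sst = sum((r - grand) ** 2 for r in ranks)
    if sst == 0.0:
        return 0.0
    ssb = 0.0
    start = 0
    for g in groups:
        part = ranks[start:start + len(g)]
        start += len(g)
        mean = sum(part) / len(part)
        ssb += len(part) * (mean - grand) ** 2
    return (N - 1) * ssb / sst


def trouvelot_indices(codes):
    """F, M, m, a, A accumulated fragment by fragment."""
    frags = []
    for code in codes:
        code = str(code).strip()
        if code == "0":
            frags.append((0, 0))
        else:
            frags.append((int(code[0]), int(code[2])))
    N = len(frags)
    colonized = [f for f in frags if f[0] > 0]
    F = 100.0 * len(colonized) / N
    wsum = sum(_MYC_WEIGHT[c] for c, _ in frags)
    M = wsum / N
    m = wsum / len(colonized) if colonized else 0.0
    a = (100.0 * sum(_MYC_WEIGHT[c] * _ARB_FACTOR[arb] for c, arb in colonized)
         / wsum) if wsum > 0 else 0.0
    A = a * M / 100.0
    return {"F": F, "M": M, "m": m, "a": a, "A": A}


def mean_se(values):
    """Spreadsheet-style mean and n-1 standard error."""
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, math.nan
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def group_compositions(total, max_groups=None):
    """All ordered compositions of `total` into >=2 parts of size >=1."""
    out = []
    for k in range(2, (max_groups or total) + 1):
        if k > total:
            break
        for cuts in combinations(range(1, total), k - 1):
            bounds = (0,) + cuts + (total,)
            out.append([bounds[i + 1] - bounds[i] for i in range(k)])
    return out
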