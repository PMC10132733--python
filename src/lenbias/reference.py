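"""Slow, transparent reference implementations used only for validation.

These deliberately share no code with the production paths: the rank-sum
reference re-ranks the pooled sample for every label assignment, and the
enrichment reference materializes both running ECDF curves position by
position in a Python loop.  They exist so tests (and the acceptance
script) can compare fast implementations against an independent route.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def wilcoxon_exact_reference(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration of label assignments.

    For each way of choosing which pooled observations carry the 'x'
    label, the Mann-Whitney U of that pseudo-sample is computed from
    freshly computed midranks; the p-value is the fraction of assignments
    whose |U - E[U]| is at least the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = list(x) + list(y)
    nx, ny = len(x), len(y)
    n = nx + ny
    mu = nx * ny / 2.0

    def u_of(labels: tuple[int, ...]) -> float:
        ranks = stats.rankdata(pooled)
        w = sum(ranks[i] for i in labels)
        return w - nx * (nx + 1) / 2.0

    u_obs = u_of(tuple(range(nx)))
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for labels in combinations(range(n), nx):
        if abs(u_of(labels) - mu) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


def ssgsea_bruteforce(expression, member_mask, alpha: float = 0.25) -> float:
    """Brute-force single-sample enrichment score via explicit ECDFs.

    Builds the ranked gene list (descending expression, ties by original
    index), then for every position i explicitly recomputes, from scratch,
    the weighted in-set cumulative fraction and the plain out-of-set
    cumulative fraction over positions 1..i.  O(N^2); validation only.
    """
    expression = np.asarray(expression, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    n = expression.size
    # descending order, stable in original index
    order = sorted(range(n), key=lambda i: (-expression[i], i))

    # ascending midrank of each expression value
    def midrank(i: int) -> float:
        v = expression[i]
        below = sum(1 for u in expression if u < v)
        equal = sum(1 for u in expression if u == v)
        return below + (equal + 1) / 2.0

    total_w = sum(midrank(i) ** alpha for i in range(n) if member_mask[i])
    n_out = n - int(member_mask.sum())
    es = 0.0
    for pos in range(1, n + 1):
        prefix = order[:pos]
        p_in = sum(midrank(i) ** alpha for i in prefix if member_mask[i]) / total_w
        p_out = sum(1 for i in prefix if not member_mask[i]) / n_out
        es += p_in - p_out
    return es
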