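"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: the Fisher oracle
works in exact integer arithmetic via math.comb, the Mann-Whitney oracle
enumerates group assignments with itertools, and the loess oracle solves
each local fit with numpy's polyfit.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

REL_TOL = 1e-7


def fisher_two_sided_oracle(m1: int, t1: int, m2: int, t2: int) -> float:
    """Two-sided Fisher exact p for [[m1, t1-m1], [m2, t2-m2]] via math.comb.

    Point probabilities are exact rationals w_k / C(N, K); a table enters the
    sum when its probability is at most the observed one within relative
    tolerance 1e-7 (the same inclusion rule the statistic is defined with).
    """
    N, K = t1 + t2, m1 + m2
    denom = math.comb(N, K)
    w_obs = math.comb(t1, m1) * math.comb(t2, m2)
    lo, hi = max(0, K - t2), min(K, t1)
    total = 0
    for k in range(lo, hi + 1):
        w = math.comb(t1, k) * math.comb(t2, K - k)
        if w <= w_obs or (w - w_obs) <= REL_TOL * w_obs:
            total += w
    return min(1.0, total / denom)


def mannwhitney_exact_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by complete itertools enumeration."""
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    mu = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    d_obs = abs(ranks[:n1].sum() - offset - mu)
    n_extreme = 0
    n_total = 0
    for comb in combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - offset
        n_total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


def loess_oracle(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local line per point, solved with np.polyfit."""
    n = len(y)
    k = max(3, math.ceil(span * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nbr = np.lexsort((np.arange(n), d))[:k]
        dmax = d[nbr].max()
        if dmax == 0:
            out[i] = y[nbr].mean()
            continue
        w = (1 - (d[nbr] / dmax) ** 3) ** 3
        keep = w > 0
        if keep.sum() < 2 or len(np.unique(x[nbr][keep])) < 2:
            out[i] = np.average(y[nbr], weights=w)
            continue
        b, a = np.polyfit(x[nbr][keep], y[nbr][keep], 1, w=np.sqrt(w[keep]))
        out[i] = a + b * x[i]
    return out
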