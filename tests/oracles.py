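"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles (explicit loops,
enumeration, closed forms) without touching the implementation it
checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import nbinom, poisson


def auc_pairwise(pvalues, is_deg) -> float:
    """AUC as the fraction of (DEG, non-DEG) pairs where the DEG has the
    smaller p-value, ties counting one half."""
    pvalues = np.asarray(pvalues, dtype=float)
    is_deg = np.asarray(is_deg, dtype=bool)
    pos = pvalues[is_deg]
    neg = pvalues[~is_deg]
    total = 0.0
    for pp in pos:
        for pn in neg:
            if pp < pn:
                total += 1.0
            elif pp == pn:
                total += 0.5
    return total / (pos.size * neg.size)


def bh_double_loop(p) -> np.ndarray:
    """Benjamini–Hochberg step-up by the definitional double loop:
    q_i = min over j with p_j >= p_i of min(1, p_j * m / rank_j), where
    rank_j counts the p-values <= p_j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    ranks = np.array([np.sum(p <= pj) for pj in p])
    q = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, p[j] * m / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(candidates)
    return q


def tmm_pair_bruteforce(yj, yr, nj, nr, trim_m=0.30, trim_a=0.05) -> float:
    """TMM factor for one sample pair with explicit trim lists and
    weights, following the written contract step by step."""
    yj = np.asarray(yj, dtype=float)
    yr = np.asarray(yr, dtype=float)
    genes = [g for g in range(yj.size) if yj[g] > 0 and yr[g] > 0]
    m_vals = {}
    a_vals = {}
    w_vals = {}
    for g in genes:
        pj, pr = yj[g] / nj, yr[g] / nr
        m_vals[g] = math.log2(pj / pr)
        a_vals[g] = 0.5 * math.log2(pj * pr)
        w_vals[g] = (nj - yj[g]) / (nj * yj[g]) + (nr - yr[g]) / (nr * yr[g])
    n = len(genes)

    def central_band(values, trim):
        lo = math.floor(n * trim) + 1
        hi = n + 1 - lo
        ranked = sorted(genes, key=lambda g: values[g])
        # midranks for ties
        rank = {}
        i = 0
        while i < n:
            j = i
            while j + 1 < n and values[ranked[j + 1]] == values[ranked[i]]:
                j += 1
            mid = (i + 1 + j + 1) / 2.0
            for t in range(i, j + 1):
                rank[ranked[t]] = mid
            i = j + 1
        return {g for g in genes if lo <= rank[g] <= hi}

    keep = central_band(m_vals, trim_m) & central_band(a_vals, trim_a)
    if not keep:
        keep = set(genes)
    num = sum(m_vals[g] / w_vals[g] for g in keep)
    den = sum(1.0 / w_vals[g] for g in keep)
    return 2.0 ** (num / den)


def average_linkage_bruteforce(dist: np.ndarray):
    """O(n^3) agglomeration: cluster distance is the mean pairwise
    distance over original members.  Returns merge steps as
    (frozenset_a, frozenset_b, height) in merge order."""
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    steps = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        steps.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return steps


def nb_loglik_scalar(y, mu, phi) -> float:
    """NB log-likelihood of one gene via scipy's pmf (Poisson at phi=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if phi == 0:
        return float(poisson.logpmf(y, mu).sum())
    r = 1.0 / phi
    p = r / (r + mu)
    return float(nbinom.logpmf(y, r, p).sum())


def grid_max_group_loglik(y_group, phi, offsets=None, n_grid=4001) -> float:
    """Maximum NB log-likelihood of one group mean by dense grid search
    with golden-section polish."""
    y_group = np.asarray(y_group, dtype=float)
    if offsets is None:
        offsets = np.zeros_like(y_group)
    from scipy.optimize import minimize_scalar

    def nll(beta):
        mu = np.exp(beta + offsets)
        return -nb_loglik_scalar(y_group, mu, phi)

    lo, hi = -10.0, 15.0
    grid = np.linspace(lo, hi, n_grid)
    vals = [nll(b) for b in grid]
    i = int(np.argmin(vals))
    res = minimize_scalar(
        nll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]),
        method="bounded", options={"xatol": 1e-12},
    )
    return -float(res.fun)
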