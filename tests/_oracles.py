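"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats


def naive_ward_heights(d: np.ndarray) -> np.ndarray:
    """O(n^3) Ward agglomeration via the Lance-Williams recursion.

    Maintains the full current dissimilarity matrix, repeatedly merges the
    closest pair and updates distances with

        d(u, v)^2 = [(|v|+|s|) d(v,s)^2 + (|v|+|t|) d(v,t)^2 - |v| d(s,t)^2]
                    / (|v| + |s| + |t|)

    for u = s U t. Returns the merge heights in merge order.
    """
    d = d.astype(float).copy()
    n = d.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    cur = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    heights = []
    next_id = n
    while len(active) > 1:
        (s, t), h = min(
            (((i, j), cur[(min(i, j), max(i, j))]) for a, i in enumerate(active) for j in active[a + 1:]),
            key=lambda kv: kv[1],
        )
        heights.append(h)
        u = next_id
        next_id += 1
        for v in active:
            if v in (s, t):
                continue
            dvs = cur[(min(v, s), max(v, s))]
            dvt = cur[(min(v, t), max(v, t))]
            dst = h
            nv, ns, nt = sizes[v], sizes[s], sizes[t]
            d2 = ((nv + ns) * dvs**2 + (nv + nt) * dvt**2 - nv * dst**2) / (nv + ns + nt)
            cur[(min(v, u), max(v, u))] = np.sqrt(max(d2, 0.0))
        sizes[u] = sizes[s] + sizes[t]
        active = [v for v in active if v not in (s, t)] + [u]
    return np.array(heights)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [m * p[order[r - 1]] / r for r in range(rank, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def permanova_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F computed by direct double loops (no shared code paths)."""
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    g = len(groups)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for grp in groups:
        idx = [i for i in range(n) if labels[i] == grp]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d[idx[a], idx[b]] ** 2
        ss_within += s / len(idx)
    if ss_within == 0:
        return np.inf
    return ((ss_total - ss_within) / (g - 1)) / (ss_within / (n - g))


def permanova_exhaustive_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Exact p by enumerating every distinct arrangement of the labels."""
    f_obs = permanova_f(d, labels)
    seen = set()
    ge = 0
    total = 0
    for perm in permutations(labels.tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        f = permanova_f(d, np.array(perm))
        if (np.isinf(f_obs) and np.isinf(f)) or (np.isfinite(f_obs) and f >= f_obs - 1e-12):
            ge += 1
    return ge / total


def within_subject_r(x: np.ndarray, y: np.ndarray, subjects: np.ndarray) -> float:
    """Subject-mean-centered Pearson correlation, via scipy.stats.pearsonr."""
    rx = np.concatenate([x[subjects == s] - x[subjects == s].mean() for s in np.unique(subjects)])
    ry = np.concatenate([y[subjects == s] - y[subjects == s].mean() for s in np.unique(subjects)])
    return stats.pearsonr(rx, ry)[0]
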