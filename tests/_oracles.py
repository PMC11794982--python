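"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (exhaustive enumeration, pairwise
closure, dense recomputation) and shares no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def gaussian_logpdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def viterbi_bruteforce(startprob, transmat, means, variances, obs):
    """Exhaustive argmax over all 2^n state paths (first max wins, i.e.
    lexicographically smallest with state 0 sorting first)."""
    obs = np.asarray(obs, dtype=float)
    n = len(obs)
    paths = np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.int64)
    logb = np.stack(
        [gaussian_logpdf(obs, means[j], variances[j]) for j in (0, 1)], axis=1
    )  # (n, 2)
    lp = np.log(startprob)[paths[:, 0]]
    lp = lp + logb[np.arange(n)[None, :], paths].sum(axis=1)
    if n > 1:
        lp = lp + np.log(transmat)[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return paths[int(np.argmax(lp))]


def merge_closure_oracle(intervals, max_gap):
    """Repeated pairwise merging until fixpoint.

    ``intervals``: iterable of (contig, strand, start, end).  Returns a
    sorted list of merged (contig, strand, start, end).
    """
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0] or a[1] != b[1]:
                    continue
                gap = max(a[2], b[2]) - min(a[3], b[3])
                if gap <= max_gap:
                    a[2] = min(a[2], b[2])
                    a[3] = max(a[3], b[3])
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(i) for i in items)


def mannwhitney_u(a, b):
    """U statistic for group a with mid-rank tie handling, by counting."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def exact_rank_p_oracle(a, b):
    """Exact two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    obs_dev = abs(mannwhitney_u(a, b) - mu)
    count = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = mannwhitney_u(pooled[mask], pooled[~mask])
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    return count / comb(n, n1)


def bh_oracle(pvals):
    """Step-up BH by the textbook formula."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / (np.arange(m) + 1)
    # running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def qc_oracle(dense):
    """Per-spot reads / detected features on a dense matrix."""
    reads = dense.sum(axis=0)
    detected = (dense > 0).sum(axis=0)
    total_features = int(((dense > 0).sum(axis=1) > 0).sum())
    return reads, detected, total_features


def spearman_oracle(x, y):
    """Spearman rho from mid-ranks via the Pearson formula."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
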