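"""Brute-force enumeration oracles for the rank tests.

These enumerate the full null distribution — every group-label assignment
for the rank-sum test, every sign pattern for the signed-rank test — and
stay completely independent of the implementation they are used to check.
Feasible only for small samples (C(n1+n2, n1) assignments, 2**n patterns).
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def mann_whitney_u(x, y):
    """Mann-Whitney U statistic of x (mid-ranks for ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def rank_sum_exact_p(x, y, alternative="two_sided"):
    """Exact rank-sum p by enumerating all C(n1+n2, n1) label assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    u_obs = mann_whitney_u(x, y)
    idx = range(pooled.size)
    us = []
    for chosen in combinations(idx, n1):
        mask = np.zeros(pooled.size, bool)
        mask[list(chosen)] = True
        us.append(mann_whitney_u(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    p_ge = np.mean(us >= u_obs - eps)
    p_le = np.mean(us <= u_obs + eps)
    if alternative == "greater":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def signed_rank_w(d):
    """Wilcoxon W+ (sum of ranks of positive differences); zeros dropped."""
    d = np.asarray(d, float)
    d = d[d != 0.0]
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def signed_rank_exact_p(d, alternative="two_sided"):
    """Exact signed-rank p by enumerating all 2**n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0.0]
    n = d.size
    w_obs = signed_rank_w(d)
    ranks = rankdata(np.abs(d))
    ws = []
    for pattern in range(2**n):
        signs = np.array([(pattern >> i) & 1 for i in range(n)], bool)
        ws.append(float(ranks[signs].sum()))
    ws = np.asarray(ws)
    eps = 1e-9
    p_ge = np.mean(ws >= w_obs - eps)
    p_le = np.mean(ws <= w_obs + eps)
    if alternative == "greater":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))
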