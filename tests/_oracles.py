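"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates the null explicitly (labelings, sign patterns,
partitions) with none of the shortcuts the package takes, so agreement is a
genuine two-route check.
"""

from __future__ import annotations

import itertools

import numpy as np


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Average ranks, written from the definition."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def mwu_statistic(x, y) -> float:
    """U for x over y, counting ties one half."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mwu_enum_p(x, y, sidedness="two-sided") -> float:
    """Exact MWU p by enumerating all C(n1+n2, n1) labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    u_obs = mwu_statistic(x, y)
    us = []
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        us.append(mwu_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_ge = (us >= u_obs - 1e-12).mean()
    p_le = (us <= u_obs + 1e-12).mean()
    if sidedness == "greater":
        return p_ge
    if sidedness == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def ks_statistic(x, y) -> float:
    """Max |ECDF difference| evaluated at every pooled point."""
    x, y = np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))
    pts = np.concatenate([x, y])
    fx = np.searchsorted(x, pts, side="right") / len(x)
    fy = np.searchsorted(y, pts, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def ks_enum_p(x, y) -> float:
    """Exact two-sample KS p by enumerating all labelings."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n, n1 = len(pooled), len(x)
    d_obs = ks_statistic(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        hits += ks_statistic(pooled[mask], pooled[~mask]) >= d_obs - 1e-12
        total += 1
    return hits / total


def signed_rank_enum_p(before, after, sidedness="two-sided") -> float:
    """Exact signed-rank p by enumerating all 2**n sign patterns."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    ranks = _rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([-1, 1], repeat=len(d))
    ]
    ts = np.asarray(ts, float)
    p_ge = (ts >= t_obs - 1e-12).mean()
    p_le = (ts <= t_obs + 1e-12).mean()
    if sidedness == "greater":
        return p_ge
    if sidedness == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def dunn_z_oracle(groups):
    """Textbook Dunn z for every pair, from the published formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = _rankdata(pooled)
    n = len(pooled)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values()) / (12 * (n - 1))
    out = []
    start = 0
    mean_ranks, sizes = [], []
    for g in groups:
        k = len(g)
        mean_ranks.append(ranks[start : start + k].mean())
        sizes.append(k)
        start += k
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j]))
            out.append((mean_ranks[i] - mean_ranks[j]) / se)
    return np.asarray(out)


def values_permutation_mc_p(a, b, n_draws, seed) -> float:
    """Monte-Carlo randomization p for |mean(a)-mean(b)| over re-partitions."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    na = len(a)
    t_obs = abs(np.mean(a) - np.mean(b))
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        hits += abs(perm[:na].mean() - perm[na:].mean()) >= t_obs - 1e-12
    return (1 + hits) / (n_draws + 1)
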