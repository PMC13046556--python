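"""Per-treatment Spearman co-activation networks and their comparison.

Each treatment group defines a complete weighted graph over the brain regions:
edge weights are Spearman rank correlations of IC/TA across that group's
individuals.  Three summaries are computed — total connectivity (sum of the
unique edge weights), per-node strength (sum of incident weights) and weighted
eigenvector centrality — and the edge-weight and strength distributions are
compared between treatments with KS, Mann-Whitney and randomization tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .data import ActivationMatrix
from .rank_stats import (
    TestResult,
    dunn_posthoc,
    kruskal_wallis_test,
    ks_two_sample_test,
    mann_whitney_test,
)

__all__ = [
    "CoactivationNetwork",
    "CentralityRanking",
    "NetworkComparison",
    "spearman_matrix",
    "build_network",
    "eigenvector_centrality",
    "rank_centrality",
    "compare_networks",
    "compare_networks_omnibus",
]

#: exhaustive re-partition null is used when C(n_a+n_b, n_a) is at most this
EXHAUSTIVE_PARTITION_LIMIT = 20_000


@dataclass
class CoactivationNetwork:
    group: str
    regions: list[str]
    edge_weights: np.ndarray        # symmetric, unit diagonal
    total_connectivity: float
    strength: np.ndarray
    eigenvector: np.ndarray
    node_activation: np.ndarray     # per-region median IC/TA (display sizing)
    n_individuals: int

    def unique_edges(self) -> np.ndarray:
        """The K(K-1)/2 off-diagonal weights, row-major upper triangle."""
        iu = np.triu_indices(len(self.regions), k=1)
        return self.edge_weights[iu]

    def edge_list(self) -> list[tuple[str, str, float]]:
        k = len(self.regions)
        return [
            (self.regions[i], self.regions[j], float(self.edge_weights[i, j]))
            for i, j in itertools.combinations(range(k), 2)
        ]


@dataclass
class CentralityRanking:
    metric: str
    order: list[str]
    tied: bool


@dataclass
class NetworkComparison:
    groups: tuple[str, str]
    target: str                     # 'edges' or 'strengths'
    results: list[TestResult]
    mode: str                       # permutation scheme: 'values' or 'individuals'

    def by_method(self, method: str) -> TestResult:
        for r in self.results:
            if r.method == method:
                return r
        raise KeyError(method)


def _spearman_full(x: np.ndarray) -> np.ndarray:
    """Full K×K Spearman matrix (scipy returns a scalar for K = 2)."""
    k = x.shape[1]
    if k == 2:
        r = stats.spearmanr(x[:, 0], x[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stats.spearmanr(x).statistic)
    np.fill_diagonal(rho, 1.0)
    return rho


def spearman_matrix(m: ActivationMatrix, group: str) -> np.ndarray:
    """Spearman correlation matrix of the regions within one group."""
    sub = m.group_values(group).to_numpy(dtype=float)
    if sub.shape[0] < 3:
        raise ValueError(f"group {group!r} has n={sub.shape[0]} < 3 individuals")
    const = np.flatnonzero(sub.std(axis=0) == 0)
    if const.size:
        raise ValueError(
            f"region {m.regions[const[0]]!r} is constant within group {group!r}"
        )
    return _spearman_full(sub)


def eigenvector_centrality(
    weights: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Weighted eigenvector centrality by power iteration, max-normalized to 1.

    Requires a symmetric nonnegative matrix with zero diagonal and at least
    one positive entry; starts from the uniform vector, so the result is
    deterministic and converges to the principal eigenvector
    (Perron-Frobenius).  Iteration runs on W + sI with a positive shift s:
    this leaves every eigenvector unchanged while guaranteeing convergence
    even when the graph is bipartite (where |λ_min| = λ_max and the unshifted
    iteration oscillates).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if np.abs(np.diag(w)).max() > 0:
        raise ValueError("diagonal must be zero")
    if w.max() == 0:
        raise ValueError("disconnected: all weights zero")
    shift = w.sum(axis=1).max()
    shifted = w + shift * np.eye(w.shape[0])
    v = np.full(w.shape[0], 1.0 / np.sqrt(w.shape[0]))
    for _ in range(max_iter):
        nxt = shifted @ v
        nxt /= np.linalg.norm(nxt)
        if np.abs(nxt - v).max() < tol:
            v = nxt
            break
        v = nxt
    else:
        resid = np.abs(shifted @ v / np.linalg.norm(shifted @ v) - v).max()
        raise RuntimeError(f"power iteration did not converge; residual {resid:.2e}")
    return v / v.max()


def build_network(
    m: ActivationMatrix, group: str, negative_policy: str = "error"
) -> CoactivationNetwork:
    """Build one group's co-activation network with all derived metrics.

    ``negative_policy`` governs eigenvector centrality when an edge weight is
    negative (the adjacency must be nonnegative): ``error`` (default — the
    studied networks are all-positive), ``abs`` (use |ρ|) or ``shift``
    (add −min weight to every edge).
    """
    rho = spearman_matrix(m, group)
    k = rho.shape[0]
    adj = rho.copy()
    np.fill_diagonal(adj, 0.0)
    strength = adj.sum(axis=1)
    total = float(adj[np.triu_indices(k, k=1)].sum())
    if (adj < 0).any():
        if negative_policy == "error":
            raise ValueError(
                f"negative edge weight in group {group!r}; pass "
                "negative_policy='abs' or 'shift' to proceed"
            )
        if negative_policy == "abs":
            eig_adj = np.abs(adj)
        elif negative_policy == "shift":
            eig_adj = adj - adj.min()
            np.fill_diagonal(eig_adj, 0.0)
        else:
            raise ValueError(f"unknown negative_policy {negative_policy!r}")
    else:
        eig_adj = adj
    return CoactivationNetwork(
        group=group,
        regions=m.regions,
        edge_weights=rho,
        total_connectivity=total,
        strength=strength,
        eigenvector=eigenvector_centrality(eig_adj),
        node_activation=np.median(m.group_values(group).to_numpy(dtype=float), axis=0),
        n_individuals=int((m.groups == group).sum()),
    )


def rank_centrality(net: CoactivationNetwork, metric: str = "strength") -> CentralityRanking:
    """Rank regions high→low by a centrality metric; ties keep region order."""
    if metric == "strength":
        scores = net.strength
    elif metric == "eigenvector":
        scores = net.eigenvector
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # stable sort on -score preserves the configured region order among ties
    order = np.argsort(-scores, kind="stable")
    tied = np.unique(scores).size < scores.size
    return CentralityRanking(metric=metric, order=[net.regions[i] for i in order], tied=tied)


def _metric_values(net: CoactivationNetwork, target: str) -> np.ndarray:
    if target == "edges":
        return net.unique_edges()
    if target == "strengths":
        return net.strength.copy()
    raise ValueError(f"unknown target {target!r}; expected 'edges' or 'strengths'")


def _values_mode_permutation_p(
    a: np.ndarray, b: np.ndarray, n_draws: int, seed: int | None
) -> tuple[float, str, int]:
    """Randomization p for |mean(a) − mean(b)| by re-partitioning the pool.

    Exhaustive over all C(n_a+n_b, n_a) partitions when feasible (p is then
    the plain tail fraction including the observed partition); otherwise
    Monte Carlo with +1 smoothing.
    """
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    t_obs = abs(a.mean() - b.mean())
    total_mean = pooled.mean()
    if comb(n, na) <= EXHAUSTIVE_PARTITION_LIMIT:
        hits = 0
        count = 0
        for idx in itertools.combinations(range(n), na):
            mean_a = pooled[list(idx)].mean()
            # mean_b follows from the pooled total
            mean_b = (total_mean * n - mean_a * na) / (n - na)
            hits += abs(mean_a - mean_b) >= t_obs - 1e-12
            count += 1
        return hits / count, "exhaustive", count
    if seed is None:
        raise ValueError("a seed is required for the Monte-Carlo null")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= t_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_draws + 1), "monte_carlo", n_draws


def _individuals_mode_permutation_p(
    m: ActivationMatrix, group_a: str, group_b: str, target: str,
    n_draws: int, seed: int | None,
) -> tuple[float, str, int]:
    """Randomization p that reassigns individuals to groups and recomputes
    both networks per draw (conservative alternative to values mode)."""
    if seed is None:
        raise ValueError("a seed is required for the Monte-Carlo null")
    sub = m.subset_by_groups({group_a, group_b})
    x = sub.values
    codes = (sub.groups == group_b).to_numpy()
    na = int((~codes).sum())

    def stat(values_a, values_b):
        ra = _spearman_full(values_a)
        rb = _spearman_full(values_b)
        np.fill_diagonal(ra, 0.0)
        np.fill_diagonal(rb, 0.0)
        iu = np.triu_indices(ra.shape[0], k=1)
        if target == "edges":
            return abs(ra[iu].mean() - rb[iu].mean())
        return abs(ra.sum(axis=1).mean() - rb.sum(axis=1).mean())

    t_obs = stat(x[~codes], x[codes])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(x.shape[0])
        if stat(x[perm[:na]], x[perm[na:]]) >= t_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_draws + 1), "monte_carlo", n_draws


def compare_networks(
    m: ActivationMatrix,
    group_a: str,
    group_b: str,
    target: str = "edges",
    n_draws: int = 999,
    seed: int | None = None,
    mode: str = "values",
    negative_policy: str = "error",
) -> NetworkComparison:
    """Compare two groups' edge-weight or strength distributions.

    Runs KS and Mann-Whitney on the two value sets (6 edge weights or K
    strengths per group) plus a randomization test of the absolute mean
    difference.  ``mode='values'`` re-partitions the pooled metric values
    into sets of the original sizes; ``mode='individuals'`` permutes the
    individual-to-group assignment and recomputes both Spearman matrices per
    draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if mode not in ("values", "individuals"):
        raise ValueError(f"unknown mode {mode!r}")
    net_a = build_network(m, group_a, negative_policy)
    net_b = build_network(m, group_b, negative_policy)
    va, vb = _metric_values(net_a, target), _metric_values(net_b, target)

    results = [ks_two_sample_test(va, vb), mann_whitney_test(va, vb)]
    if mode == "values":
        p, perm_mode, count = _values_mode_permutation_p(va, vb, n_draws, seed)
    else:
        p, perm_mode, count = _individuals_mode_permutation_p(
            m, group_a, group_b, target, n_draws, seed
        )
    results.append(
        TestResult(
            method="permutation",
            statistic_name="D",
            statistic=float(abs(va.mean() - vb.mean())),
            p_value=float(p),
            mode=perm_mode,
            n_per_group=[int(va.size), int(vb.size)],
        )
    )
    return NetworkComparison(groups=(group_a, group_b), target=target,
                             results=results, mode=mode)


def compare_networks_omnibus(
    m: ActivationMatrix,
    target: str = "edges",
    adjust: str = "bh",
    negative_policy: str = "error",
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis across all groups' metric value sets, plus Dunn pairs."""
    labels = m.group_labels
    nets = [build_network(m, g, negative_policy) for g in labels]
    sets = [_metric_values(n, target) for n in nets]
    kw = kruskal_wallis_test(sets)
    dunn = dunn_posthoc(sets, labels=labels, adjust=adjust)
    return kw, dunn
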