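"""Rank-based tests, effect sizes and multiplicity correction.

All tests use average ranks for ties and record whether their p-value came
from an exact null distribution, a normal/chi-squared approximation, or Monte
Carlo, so downstream reports always carry the computation mode alongside the
number.  Exact modes are used automatically whenever the sample sizes permit:
these are 6–9 animals per group, where asymptotic references are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "EffectSize",
    "mann_whitney_test",
    "wilcoxon_signed_rank_test",
    "kruskal_wallis_test",
    "dunn_posthoc",
    "ks_two_sample_test",
    "adjust_bh_fdr",
    "effect_size",
]

_SIDES = ("two-sided", "greater", "less")

#: largest n1*n2 for which the Mann-Whitney null is enumerated exactly
MWU_EXACT_LIMIT = 2_000
#: largest n1*n2 for which the KS null is evaluated by lattice-path counting
KS_EXACT_LIMIT = 10_000
#: largest n for which the signed-rank null is enumerated over 2**n sign patterns
SIGNED_RANK_EXACT_LIMIT = 20


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, and full provenance."""

    method: str
    statistic_name: str
    statistic: float
    p_value: float
    sidedness: str = "two-sided"
    mode: str = "exact"
    n_per_group: list[int] = field(default_factory=list)
    df: int | None = None
    pair: tuple[str, str] | None = None
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "mode": self.mode,
            "n_per_group": list(self.n_per_group),
        }
        if self.df is not None:
            d["df"] = self.df
        if self.pair is not None:
            d["pair"] = list(self.pair)
        if self.p_adjusted is not None:
            d["p_adjusted"] = self.p_adjusted
        return d


@dataclass
class EffectSize:
    """Standardized mean difference (Cohen's d or Hedges' g)."""

    kind: str
    value: float
    n1: int
    n2: int


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    return arr


def _check_side(sidedness: str) -> str:
    if sidedness not in _SIDES:
        raise ValueError(f"sidedness must be one of {_SIDES}, got {sidedness!r}")
    return sidedness


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_test(x, y, sidedness: str = "two-sided", mode: str | None = None) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney U test.

    The statistic is U for ``x`` over ``y``: the number of (x_i, y_j) pairs
    with x_i > y_j, counting ties as 1/2.  By default the p-value is exact
    (enumeration over all labelings) when the pooled sample has no ties and
    ``n1 * n2 <= 2000``, otherwise a tie-corrected normal approximation with
    continuity correction; pass ``mode='exact'`` or ``mode='asymptotic'`` to
    force one.
    """
    x, y = _as_sample(x, "x"), _as_sample(y, "y")
    side = _check_side(sidedness)
    if mode is None:
        exact = not _has_ties(np.concatenate([x, y])) and x.size * y.size <= MWU_EXACT_LIMIT
    elif mode in ("exact", "asymptotic"):
        exact = mode == "exact"
    else:
        raise ValueError(f"mode must be None, 'exact' or 'asymptotic', got {mode!r}")
    res = stats.mannwhitneyu(
        x, y, alternative=side, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        method="mann_whitney",
        statistic_name="U",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=side,
        mode="exact" if exact else "asymptotic",
        n_per_group=[int(x.size), int(y.size)],
    )


def _signed_rank_exact_p(ranks: np.ndarray, t_plus: float, side: str) -> float:
    """Exact signed-rank p over all 2**n sign assignments.

    Works on doubled ranks (integers even under average-rank ties) with a
    subset-sum distribution, so tied |differences| are handled exactly.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    t2 = int(np.rint(2 * t_plus))
    p_le = float(dist[: t2 + 1].sum())
    p_ge = float(dist[t2:].sum())
    if side == "greater":
        return p_ge
    if side == "less":
        return p_le
    return min(1.0, 2 * min(p_le, p_ge))


def wilcoxon_signed_rank_test(before, after, sidedness: str = "two-sided") -> TestResult:
    """Paired Wilcoxon signed-rank test on ``after - before``.

    Zero differences are dropped; T is the sum of the ranks of the positive
    differences among the ranked |differences|.  Exact sign-enumeration null
    for n <= 20 (ties in |differences| handled via average ranks), normal
    approximation with tie correction beyond.
    """
    before, after = _as_sample(before, "before"), _as_sample(after, "after")
    side = _check_side(sidedness)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate paired sample: all differences zero")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= SIGNED_RANK_EXACT_LIMIT:
        p = _signed_rank_exact_p(ranks, t_plus, side)
        mode = "exact"
    else:
        mu = n * (n + 1) / 4
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
        z = (t_plus - mu - 0.5 * np.sign(t_plus - mu)) / np.sqrt(sigma2)
        if side == "greater":
            p = float(stats.norm.sf(z))
        elif side == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        mode = "asymptotic"
    return TestResult(
        method="wilcoxon_signed_rank",
        statistic_name="T",
        statistic=t_plus,
        p_value=min(1.0, p),
        sidedness=side,
        mode=mode,
        n_per_group=[int(n)],
    )


def kruskal_wallis_test(groups) -> TestResult:
    """Kruskal-Wallis H test across k >= 2 groups.

    Average ranks with tie correction; p from the chi-squared reference with
    df = k - 1.  An all-tied input returns H = 0, p = 1 rather than erroring,
    so pipelines on degenerate draws do not crash.
    """
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis_test needs at least 2 groups")
    k = len(samples)
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return TestResult(
        method="kruskal_wallis",
        statistic_name="H",
        statistic=float(h),
        p_value=float(p),
        mode="asymptotic",
        n_per_group=[int(s.size) for s in samples],
        df=k - 1,
    )


def dunn_posthoc(groups, labels=None, adjust: str = "bh") -> list[TestResult]:
    """Dunn's post hoc z-tests on mean ranks after a Kruskal-Wallis test.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    term T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values, optionally
    BH-adjusted across the pairs.
    """
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2:
        raise ValueError("dunn_posthoc needs at least 2 groups")
    if adjust not in ("bh", "none"):
        raise ValueError(f"adjust must be 'bh' or 'none', got {adjust!r}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(samples))]
    pooled = np.concatenate(samples)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12 * (n_tot - 1))
    sizes = [s.size for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(samples))]
    var_base = n_tot * (n_tot + 1) / 12 - tie_term

    results = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2 * stats.norm.sf(abs(z)))
            results.append(
                TestResult(
                    method="dunn",
                    statistic_name="z",
                    statistic=float(z),
                    p_value=p,
                    mode="asymptotic",
                    n_per_group=[sizes[i], sizes[j]],
                    pair=(labels[i], labels[j]),
                )
            )
    raw = [r.p_value for r in results]
    adj = adjust_bh_fdr(raw) if adjust == "bh" else raw
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


def ks_two_sample_test(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute ECDF difference over all pooled points; exact
    (lattice-path) p for n1 * n2 <= 10,000, else the asymptotic distribution.
    """
    x, y = _as_sample(x, "x"), _as_sample(y, "y")
    exact = x.size * y.size <= KS_EXACT_LIMIT
    res = stats.ks_2samp(x, y, method="exact" if exact else "asymp")
    return TestResult(
        method="ks_two_sample",
        statistic_name="D",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mode="exact" if exact else "asymptotic",
        n_per_group=[int(x.size), int(y.size)],
    )


def adjust_bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="fdr_bh")[1]]


def effect_size(x, y, kind: str = "auto") -> EffectSize:
    """Cohen's d or Hedges' g for two samples.

    ``auto`` picks d for balanced comparisons (n1 == n2) and the
    small-sample-corrected g otherwise.  Pooled SD uses n−1 denominators.
    """
    x, y = _as_sample(x, "x"), _as_sample(y, "y")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("effect sizes need at least 2 observations per sample")
    if kind not in ("cohens_d", "hedges_g", "auto"):
        raise ValueError(f"unknown effect-size kind {kind!r}")
    if kind == "auto":
        kind = "cohens_d" if n1 == n2 else "hedges_g"
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero variance: effect size undefined")
    d = (x.mean() - y.mean()) / np.sqrt(pooled_var)
    if kind == "hedges_g":
        d *= 1 - 3 / (4 * (n1 + n2) - 9)
    return EffectSize(kind=kind, value=float(d), n1=int(n1), n2=int(n2))
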