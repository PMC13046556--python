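"""PCA on the regional activation profile and Euclidean-distance PERMANOVA.

PCA summarizes the four-region IC/TA profile per individual; PERMANOVA asks
whether the multivariate profiles differ between treatment groups, using the
pseudo-F of the Euclidean distance matrix and a label-permutation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import ActivationMatrix
from .rank_stats import adjust_bh_fdr

__all__ = [
    "PCAResult",
    "PermanovaResult",
    "pca_fit",
    "permanova_euclidean",
    "pairwise_permanova",
]


@dataclass
class PCAResult:
    """Loadings, per-component spread and variance fractions, and scores."""

    regions: list[str]
    loadings: np.ndarray          # regions × components, unit-norm columns
    sdev: np.ndarray              # per-component standard deviation
    proportion: np.ndarray        # variance fraction per component
    cumulative: np.ndarray
    scores: np.ndarray            # individuals × components
    standardized: bool

    def to_frame(self) -> pd.DataFrame:
        """Summary table: sdev / proportion / cumulative rows, then one
        loading row per region; one column per principal component."""
        cols = [f"PC{i + 1}" for i in range(len(self.sdev))]
        rows = np.vstack([self.sdev, self.proportion, self.cumulative, self.loadings])
        index = ["Standard deviation", "Proportion of variance", "Cumulative proportion"]
        return pd.DataFrame(rows, index=index + list(self.regions), columns=cols)


@dataclass
class PermanovaResult:
    pseudo_F: float
    n_permutations: int
    p_value: float
    group_labels: list[str]
    seed: int | None = None
    pairwise: list[dict] | None = None

    def to_dict(self) -> dict:
        d = {
            "pseudo_F": self.pseudo_F,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "group_labels": list(self.group_labels),
            "seed": self.seed,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise
        return d


def pca_fit(m: ActivationMatrix, standardize: bool = True) -> PCAResult:
    """Principal component analysis of the individuals × regions matrix.

    With ``standardize`` (default) the analysis is on the correlation matrix:
    regions differ in IC/TA scale, and standardizing weights them equally.
    Components come from the spectral decomposition; each is sign-flipped so
    its largest-|loading| entry is positive, making the output deterministic
    (principal axes are otherwise defined only up to sign).
    """
    x = m.values
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 individuals")
    centered = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if standardize:
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise ValueError(
                f"constant region column {m.regions[const[0]]!r}: cannot standardize"
            )
        centered = centered / sd
    cov = np.cov(centered, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    total = eigval.sum()
    prop = eigval / total if total > 0 else np.zeros_like(eigval)
    return PCAResult(
        regions=m.regions,
        loadings=eigvec,
        sdev=np.sqrt(eigval),
        proportion=prop,
        cumulative=np.cumsum(prop),
        scores=centered @ eigvec,
        standardized=standardize,
    )


def _group_codes(m: ActivationMatrix) -> tuple[np.ndarray, list[str]]:
    labels = m.group_labels
    lut = {g: i for i, g in enumerate(labels)}
    return np.array([lut[g] for g in m.groups], dtype=int), labels


def pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and group codes.

    SS_total = Σ_{i<j} d²ij / N; SS_within = Σ_g Σ_{i<j∈g} d²ij / n_g;
    F = (SS_between/(a−1)) / (SS_within/(N−a)).
    """
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    return float((ss_between / (n_groups - 1)) / (ss_within / (n - n_groups)))


def _permuted_pseudo_f(d2: np.ndarray, perm_codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized pseudo-F for a batch of permuted label rows (P × N)."""
    n = perm_codes.shape[1]
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(perm_codes.shape[0])
    for g in range(n_groups):
        mask = (perm_codes == g).astype(float)
        n_g = mask[0].sum()  # group sizes are permutation-invariant
        ss_within += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2 * n_g)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova_euclidean(
    m: ActivationMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on the Euclidean distance matrix of the profiles.

    The null is formed by uniformly permuting group labels; the reported
    p = (1 + #{F* >= F_obs}) / (B + 1) counts the observed labeling once, so
    p is never 0 and lives on the grid {k/(B+1)}.  With ``exhaustive`` the
    null enumerates every distinct assignment of individuals to group sizes
    (two-group designs only) and p is the plain enumeration tail.
    """
    codes, labels = _group_codes(m)
    if len(labels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 members")
    d2 = squareform(pdist(m.values, metric="sqeuclidean"))
    if d2.sum() == 0:
        raise ValueError("zero total dispersion: all rows identical")
    f_obs = pseudo_f(d2, codes, len(labels))

    if exhaustive:
        if len(labels) != 2:
            raise ValueError("exhaustive mode supports exactly 2 groups")
        n = len(codes)
        n0 = int(sizes[0])
        fs = []
        for idx in itertools.combinations(range(n), n0):
            c = np.ones(n, dtype=int)
            c[list(idx)] = 0
            fs.append(pseudo_f(d2, c, 2))
        fs = np.asarray(fs)
        p = float((fs >= f_obs - 1e-12).sum() / fs.size)
        return PermanovaResult(f_obs, fs.size, p, labels, seed=None)

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_permutations, len(codes))), axis=1)
    perm_codes = codes[order]
    f_perm = _permuted_pseudo_f(d2, perm_codes, len(labels))
    p = float((1 + (f_perm >= f_obs - 1e-12).sum()) / (n_permutations + 1))
    return PermanovaResult(f_obs, n_permutations, p, labels, seed=seed)


def pairwise_permanova(
    m: ActivationMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    adjust: str = "none",
) -> PermanovaResult:
    """Overall PERMANOVA plus one two-group PERMANOVA per group pair.

    Pairwise p-values are reported raw by default (``adjust="bh"`` adds a
    BH-adjusted column).  Each pair runs on an independent, deterministic
    substream of ``seed``.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    overall = permanova_euclidean(m, n_permutations, seed)
    labels = m.group_labels
    pairs = list(itertools.combinations(labels, 2))
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (a, b), child in zip(pairs, children):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        res = permanova_euclidean(m.subset_by_groups({a, b}), n_permutations, sub_seed)
        rows.append({"pair": [a, b], "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                     "seed": sub_seed})
    if adjust == "bh":
        adj = adjust_bh_fdr([r["p_value"] for r in rows])
        for r, pa in zip(rows, adj):
            r["p_adjusted"] = pa
    overall.pairwise = rows
    return overall
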