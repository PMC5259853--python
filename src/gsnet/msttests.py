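"""MST-based nonparametric two-sample tests for gene sets.

Five tests over the Euclidean MST of the pooled samples:

* ``ww_test`` — multivariate Wald-Wolfowitz (runs) test of equality of
  distributions.  Cross-group MST edges are deleted; the standardized count
  of remaining disjoint subtrees W = (R - E[R]) / sd(R) is the statistic
  and the null is rejected for few subtrees.
* ``ks_test`` / ``md_test`` — multivariate Kolmogorov-Smirnov and mean
  deviation tests of equal means, computed on the HDP ranking of the MST.
* ``rks_test`` / ``rmd_test`` — the radial variants, computed on the radial
  ranking of the MST (or of the union of the first ``mst_order`` MSTs),
  aimed at scale (variance) alternatives.

All p-values are permutation estimates with the +1/(M+1) correction.  The
tree and the vertex ranking depend on the data geometry only, so they are
built once and the labels are permuted over fixed ranks.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ExpressionMatrix, check_labels
from .graphs import (
    build_mst,
    count_disjoint_subtrees,
    hdp_ranking,
    mst_union,
    pairwise_euclidean,
    radial_ranking,
)
from .permutation import TestResult, generate_permutations, perm_pvalue

__all__ = [
    "ks_statistic",
    "md_statistic",
    "ww_test",
    "mst_rank_test",
    "ks_test",
    "md_test",
    "rks_test",
    "rmd_test",
    "scale_specific_filter",
]

DEFAULT_MD_ALPHA = 0.25


def _check_ranks(ranks) -> np.ndarray:
    ranks = np.asarray(ranks, dtype=int)
    n = ranks.shape[0]
    if not np.array_equal(np.sort(ranks), np.arange(1, n + 1)):
        raise ValueError("ranks must be a permutation of 1..N")
    return ranks


def _labels_in_rank_order(ranks, label_rows) -> np.ndarray:
    """Rows of labels reordered so column i holds the label of the rank-i sample."""
    order = np.argsort(ranks)
    return np.atleast_2d(label_rows)[:, order]


def _ks_batch(ranks, label_rows) -> np.ndarray:
    """KS statistic D for each row of a label matrix, over fixed ranks.

    d_i = r_i/n1 - s_i/n2 where r_i (s_i) counts group-1 (group-2) samples
    with rank <= i; D = sqrt(n1 n2 / N) * max_i |d_i|.
    """
    lro = _labels_in_rank_order(ranks, label_rows)
    n = lro.shape[1]
    in1 = lro == 1
    n1 = in1[0].sum()
    n2 = n - n1
    r = np.cumsum(in1, axis=1)
    s = np.cumsum(~in1, axis=1)
    d = r / n1 - s / n2
    return np.sqrt(n1 * n2 / n) * np.max(np.abs(d), axis=1)


def _md_batch(ranks, label_rows, alpha=DEFAULT_MD_ALPHA) -> np.ndarray:
    """Signed MD statistic for each row of a label matrix, over fixed ranks.

    P(X, i) is the rank-weighted CDF of group 1 (weights rank^alpha);
    P(Y, i) the unweighted CDF of group 2; D = sum_i [P(X,i) - P(Y,i)],
    summed over the N sample ranks.
    """
    lro = _labels_in_rank_order(ranks, label_rows)
    n = lro.shape[1]
    in1 = lro == 1
    n2 = n - in1[0].sum()
    w = np.arange(1, n + 1, dtype=float) ** alpha
    xw = in1 * w
    px = np.cumsum(xw, axis=1) / np.sum(xw, axis=1, keepdims=True)
    py = np.cumsum(~in1, axis=1) / n2
    return np.sum(px - py, axis=1)


def ks_statistic(ranks, labels) -> float:
    """Multivariate KS statistic of one labeling over an MST ranking."""
    ranks = _check_ranks(ranks)
    labels = check_labels(labels, ranks.shape[0])
    return float(_ks_batch(ranks, labels[None, :])[0])


def md_statistic(ranks, labels, alpha: float = DEFAULT_MD_ALPHA) -> float:
    """Signed mean-deviation statistic of one labeling over an MST ranking.

    Group 1 plays the role of X (rank-weighted CDF with exponent ``alpha``,
    default 0.25 to give the ranks a modest weight); group 2 of Y.  The
    two-sided test uses |D|.
    """
    ranks = _check_ranks(ranks)
    labels = check_labels(labels, ranks.shape[0])
    return float(_md_batch(ranks, labels[None, :], alpha=alpha)[0])


def _prepare(expr, labels):
    if not isinstance(expr, ExpressionMatrix):
        expr = ExpressionMatrix(np.asarray(expr, dtype=float))
    labels = check_labels(labels, expr.n_samples)
    return expr, labels


def ww_test(expr, labels, nperm: int = 1000, seed=None, exhaustive: str = "auto") -> TestResult:
    """Multivariate Wald-Wolfowitz test: H0 F_X = F_Y vs H1 F_X != F_Y.

    The MST of the pooled samples is built once; the runs statistic R is
    the number of disjoint subtrees after deleting cross-group edges.  E[R]
    and sd(R) are estimated from the permutation sample, and the p-value is
    the lower-tail permutation estimate — identical on W and on raw R,
    since W is a fixed increasing transform of R.
    """
    expr, labels = _prepare(expr, labels)
    tree = build_mst(pairwise_euclidean(expr))
    edges = np.array(tree.edges(), dtype=int)
    u, v = edges[:, 0], edges[:, 1]

    r_obs = count_disjoint_subtrees(tree, labels)
    perms, is_exh = generate_permutations(labels, nperm, seed=seed, exhaustive=exhaustive)
    r_perm = np.sum(perms[:, u] != perms[:, v], axis=1) + 1

    mean_r = float(np.mean(r_perm))
    sd_r = float(np.std(r_perm, ddof=1)) if r_perm.size > 1 else 0.0
    if sd_r > 0:
        w_obs = (r_obs - mean_r) / sd_r
        w_perm = (r_perm - mean_r) / sd_r
    else:
        warnings.warn(
            "all permuted subtree counts identical (sd(R) = 0); "
            "p-value computed on the raw runs statistic R",
            RuntimeWarning,
            stacklevel=2,
        )
        w_obs = float(r_obs)
        w_perm = r_perm.astype(float)
    p = perm_pvalue(w_obs, w_perm, side="lower")
    return TestResult(
        p_value=p,
        observed_stat=w_obs,
        perm_stats=w_perm,
        method="ww",
        nperm=perms.shape[0],
        seed=None if is_exh else seed,
        exhaustive=is_exh,
        extras={"R": int(r_obs), "mean_R": mean_r, "sd_R": sd_r, "R_perm": r_perm},
    )


def mst_rank_test(
    expr,
    labels,
    stat: str = "ks",
    ranking: str = "hdp",
    mst_order: int = 1,
    nperm: int = 1000,
    seed=None,
    alpha: float = DEFAULT_MD_ALPHA,
    exhaustive: str = "auto",
) -> TestResult:
    """Rank-based MST test; the four named tests are fixed (stat, ranking) pairs.

    ``hdp`` ranking requires ``mst_order == 1``; ``radial`` ranking accepts
    1 <= mst_order <= 5 and then ranks the union of the first ``mst_order``
    MSTs.  KS uses the upper-tail p-value, MD the two-sided |D| p-value.
    """
    stat = stat.lower()
    ranking = ranking.lower()
    if stat not in ("ks", "md"):
        raise ValueError(f"stat must be 'ks' or 'md', got {stat!r}")
    if ranking not in ("hdp", "radial"):
        raise ValueError(f"ranking must be 'hdp' or 'radial', got {ranking!r}")
    if ranking == "hdp" and mst_order != 1:
        raise ValueError("hdp ranking is defined on the first MST only (mst_order = 1)")
    expr, labels = _prepare(expr, labels)
    dist = pairwise_euclidean(expr)
    if ranking == "hdp":
        ranks = hdp_ranking(build_mst(dist))
    else:
        graph = build_mst(dist) if mst_order == 1 else mst_union(dist, mst_order)
        ranks = radial_ranking(graph)

    batch = _ks_batch if stat == "ks" else (lambda r, L: _md_batch(r, L, alpha=alpha))
    d_obs = float(batch(ranks, labels[None, :])[0])
    perms, is_exh = generate_permutations(labels, nperm, seed=seed, exhaustive=exhaustive)
    d_perm = batch(ranks, perms)
    side = "upper" if stat == "ks" else "two_sided_abs"
    p = perm_pvalue(d_obs, d_perm, side=side)
    method = ("" if ranking == "hdp" else "r") + stat
    return TestResult(
        p_value=p,
        observed_stat=d_obs,
        perm_stats=d_perm,
        method=method,
        nperm=perms.shape[0],
        seed=None if is_exh else seed,
        exhaustive=is_exh,
        extras={"ranking": ranking, "mst_order": mst_order, "ranks": ranks},
    )


def ks_test(expr, labels, nperm: int = 1000, seed=None, **kw) -> TestResult:
    """KS test of equal multivariate means (HDP ranking)."""
    return mst_rank_test(expr, labels, stat="ks", ranking="hdp", nperm=nperm, seed=seed, **kw)


def md_test(expr, labels, nperm: int = 1000, seed=None, **kw) -> TestResult:
    """Mean-deviation test of equal multivariate means (HDP ranking)."""
    return mst_rank_test(expr, labels, stat="md", ranking="hdp", nperm=nperm, seed=seed, **kw)


def rks_test(expr, labels, mst_order: int = 1, nperm: int = 1000, seed=None, **kw) -> TestResult:
    """Radial KS test of equal dispersion (radial ranking, optional k-MST union)."""
    return mst_rank_test(
        expr, labels, stat="ks", ranking="radial", mst_order=mst_order, nperm=nperm, seed=seed, **kw
    )


def rmd_test(expr, labels, mst_order: int = 1, nperm: int = 1000, seed=None, **kw) -> TestResult:
    """Radial mean-deviation test of equal dispersion."""
    return mst_rank_test(
        expr, labels, stat="md", ranking="radial", mst_order=mst_order, nperm=nperm, seed=seed, **kw
    )


def scale_specific_filter(p_radial: float, p_shift: float, alpha: float = 0.05) -> bool:
    """Variance-specific call: radial test significant, shift test not.

    True iff ``p_radial < alpha`` and ``p_shift > alpha`` — the joint rule
    that keeps gene sets whose dispersion differs while their means do not.
    Use RKS with KS, or RMD with MD.
    """
    for name, p in (("p_radial", p_radial), ("p_shift", p_shift)):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return p_radial < alpha and p_shift > alpha
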