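"""Aggregated F-test of differential variability (AggrFtest).

Each gene gets a two-sided variance-ratio F p-value; Fisher's method
combines them into T = -2 sum ln P_i, and significance of T is estimated by
permuting sample labels (gene p-values are correlated in expression data,
so the chi-square reference with 2p degrees of freedom only holds under
independence and is not used for inference).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, check_labels
from .permutation import TestResult, generate_permutations, perm_pvalue

__all__ = ["gene_f_pvalue", "fisher_aggregate", "aggr_f_test"]

_P_FLOOR = np.finfo(float).tiny


def gene_f_pvalue(x_row, y_row) -> float:
    """Two-sided p-value of the variance-ratio F test for one gene.

    F = s2_x / s2_y with unbiased sample variances, referred to the
    F(n1 - 1, n2 - 1) distribution; the null of equal variances is rejected
    when F is too large or too small, so the p-value doubles the smaller
    tail (capped at 1).  If both variances are zero there is no evidence
    either way and the p-value is 1, with a warning.
    """
    x = np.asarray(x_row, dtype=float)
    y = np.asarray(y_row, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    s2x = float(np.var(x, ddof=1))
    s2y = float(np.var(y, ddof=1))
    if s2x == 0 and s2y == 0:
        warnings.warn("both group variances are zero; F undefined, p = 1", RuntimeWarning, stacklevel=2)
        return 1.0
    if s2y == 0:
        return 0.0  # infinite ratio: maximal evidence; callers floor before log
    f = s2x / s2y
    dist = stats.f(x.size - 1, y.size - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def fisher_aggregate(pvals) -> float:
    """Fisher's combined statistic T = -2 sum ln P_i (>= 0).

    Under p independent uniform p-values T ~ chi-square with 2p df.  Any
    zero p-value makes the log undefined; callers must floor at the
    smallest positive float first.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to aggregate")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.sum(np.log(p)))


def _group_variances(values, label_rows):
    """Unbiased per-gene variances within each group for every label row.

    Returns (s2x, s2y), each of shape (n_label_rows, p).  Vectorized over
    permutations via sums of x and x^2 against group-membership masks.
    """
    lab = np.atleast_2d(label_rows)
    v = values  # (p, N)
    v2 = v * v
    out = []
    for g in (1, 2):
        mask = (lab == g).astype(float)  # (M, N)
        n = mask.sum(axis=1, keepdims=True)  # (M, 1)
        s = mask @ v.T  # (M, p)
        s2 = mask @ v2.T
        var = (s2 - s * s / n) / (n - 1)
        out.append(np.maximum(var, 0.0))  # clamp tiny negative rounding
    return out[0], out[1]


def _fisher_t_batch(values, label_rows) -> np.ndarray:
    """Fisher T for each label row; zero-division and p=0 handled by flooring."""
    lab = np.atleast_2d(label_rows)
    s2x, s2y = _group_variances(values, lab)
    n1 = int(np.sum(lab[0] == 1))
    n2 = lab.shape[1] - n1
    fdist = stats.f(n1 - 1, n2 - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = s2x / s2y
        pv = 2.0 * np.minimum(fdist.cdf(f), fdist.sf(f))
        pv = np.where(s2y == 0, np.where(s2x == 0, 1.0, 0.0), pv)
    pv = np.clip(pv, _P_FLOOR, 1.0)
    return -2.0 * np.sum(np.log(pv), axis=1)


def aggr_f_test(expr, labels, nperm: int = 1000, seed=None, exhaustive: str = "auto") -> TestResult:
    """AggrFtest: does any gene in the set change variance between groups?

    Tests H0: sigma_Xi = sigma_Yi for all i against H1: sigma_Xi != sigma_Yi
    for some i.  All gene F p-values and the Fisher statistic T are
    recomputed under each label permutation; the p-value is the upper-tail
    permutation estimate (Sum I[T_k >= T_obs] + 1) / (M + 1).  Per-gene
    p-values are floored at the smallest positive float before taking logs
    so zero-variance genes under permutation never produce -inf.
    """
    if not isinstance(expr, ExpressionMatrix):
        expr = ExpressionMatrix(np.asarray(expr, dtype=float))
    labels = check_labels(labels, expr.n_samples)
    t_obs = float(_fisher_t_batch(expr.values, labels[None, :])[0])
    perms, is_exh = generate_permutations(labels, nperm, seed=seed, exhaustive=exhaustive)
    t_perm = _fisher_t_batch(expr.values, perms)
    p = perm_pvalue(t_obs, t_perm, side="upper")
    return TestResult(
        p_value=p,
        observed_stat=t_obs,
        perm_stats=t_perm,
        method="aggrf",
        nperm=perms.shape[0],
        seed=None if is_exh else seed,
        exhaustive=is_exh,
    )
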