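"""Gene Sets Net Correlation Analysis (GSNCA).

GSNCA compares the *structure* of intergene correlations between two
conditions rather than their overall level.  Within each condition every
gene i receives a weight w_i satisfying

    w_i = sum_{j != i} w_j |r_ij|

where r_ij is the correlation between genes i and j.  The solution is the
leading eigenvector of the zero-diagonal matrix of absolute correlations
(Perron-Frobenius: positive for an irreducible nonnegative matrix).  The
test statistic is the L1 distance between the two weight vectors, each
scaled to mean 1; it is exactly zero when the two conditions share one
correlation matrix up to a constant factor, so a uniform inflation of all
correlations is invisible — only relative rearrangements are detected.

Because correlations are undefined for constant genes (a real concern for
RNA-seq counts, where non-expressed genes are zero across most samples),
the test guards on per-gene standard deviations: an error for the observed
grouping, and a bounded number of skipped permutations otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import ExpressionMatrix, check_labels
from .permutation import TestResult, generate_permutations, perm_pvalue

__all__ = [
    "GSNCAConfig",
    "intergene_correlation",
    "gene_weights",
    "gsnca_statistic",
    "gsnca_test",
]

_COR_METHODS = ("pearson", "spearman", "kendall")


@dataclass(frozen=True)
class GSNCAConfig:
    """Guard and correlation settings for :func:`gsnca_test`.

    check_sd
        Check per-gene standard deviations before computing correlations.
    min_sd
        Smallest allowed within-group gene SD (default 1e-3).
    max_skip
        Maximum number of label permutations that may be skipped because
        they push some gene's within-group SD below ``min_sd``.
    cor_method
        pearson (default), spearman or kendall.
    """

    check_sd: bool = True
    min_sd: float = 1e-3
    max_skip: int = 10
    cor_method: str = "pearson"

    def __post_init__(self):
        if self.min_sd <= 0:
            raise ValueError("min_sd must be > 0")
        if self.max_skip < 0:
            raise ValueError("max_skip must be >= 0")
        if self.cor_method not in _COR_METHODS:
            raise ValueError(f"cor_method must be one of {_COR_METHODS}")


class LowVarianceError(ValueError):
    """A gene's within-group standard deviation fell below min_sd."""

    def __init__(self, n_genes: int, where: str):
        self.n_genes = n_genes
        super().__init__(
            f"{n_genes} feature(s) with standard deviation below min_sd in {where}; "
            "filter non-expressed genes or disable check_sd"
        )


def intergene_correlation(group_values, method: str = "pearson", gene_ids=None) -> np.ndarray:
    """p x p correlation matrix of gene rows within one condition.

    Raises a descriptive error naming the first offending gene if any row
    has zero variance (the correlation is undefined there).
    """
    values = np.asarray(getattr(group_values, "values", group_values), dtype=float)
    if method not in _COR_METHODS:
        raise ValueError(f"method must be one of {_COR_METHODS}")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        idx = int(np.argmin(sd))
        name = gene_ids[idx] if gene_ids is not None else f"row {idx}"
        raise ValueError(f"gene {name} has zero variance; correlation undefined")
    if method == "pearson":
        return np.corrcoef(values)
    # spearman/kendall on within-condition ranks; pandas averages ties
    return pd.DataFrame(values.T).corr(method=method).to_numpy()


def gene_weights(corr: np.ndarray) -> np.ndarray:
    """Positive leading eigenvector of the zero-diagonal |r| matrix, mean 1.

    Solves w_i = sum_{j != i} w_j |r_ij| as an eigenproblem.  If the
    absolute-correlation graph is reducible (a gene uncorrelated with all
    others gives a zero row and the Perron vector need not be positive),
    off-diagonals are perturbed by 1e-12 to restore irreducibility.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != p:
        raise ValueError("correlation matrix must be square")
    if p < 2:
        raise ValueError("need at least 2 genes")
    a = np.abs(corr).astype(float)
    np.fill_diagonal(a, 0.0)
    if np.any(a.sum(axis=1) == 0):
        a = a + 1e-12
        np.fill_diagonal(a, 0.0)
    vals, vecs = linalg.eigh(a)
    w = vecs[:, -1]
    # Perron vector: fix the sign so entries are positive
    if w.sum() < 0:
        w = -w
    w = np.abs(w)
    return w * (p / w.sum())


def gsnca_statistic(w1, w2) -> float:
    """L1 distance between two mean-1 gene weight vectors."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError(f"weight vectors differ in length: {w1.shape} vs {w2.shape}")
    return float(np.sum(np.abs(w1 - w2)))


def _stat_for_labels(values, labels, method):
    w = []
    for g in (1, 2):
        corr = intergene_correlation(values[:, labels == g], method=method)
        w.append(gene_weights(corr))
    return gsnca_statistic(w[0], w[1]), w


def _low_sd_count(values, labels, min_sd) -> int:
    bad = np.zeros(values.shape[0], dtype=bool)
    for g in (1, 2):
        bad |= values[:, labels == g].std(axis=1, ddof=1) < min_sd
    return int(bad.sum())


def gsnca_test(
    expr,
    labels,
    config: GSNCAConfig | None = None,
    nperm: int = 1000,
    seed=None,
    exhaustive: str = "auto",
) -> TestResult:
    """GSNCA permutation test: H0 w_GSNCA = 0 vs H1 w_GSNCA != 0.

    Per-condition gene weights and their L1 distance are recomputed under
    each label permutation; the p-value is the upper-tail estimate.  With
    ``config.check_sd`` the observed grouping must satisfy the minimum-SD
    guard (error naming the number of offending genes otherwise), and up to
    ``config.max_skip`` permutations that violate it are skipped (sampled
    mode redraws them; exhaustive mode drops them) before the test aborts.
    """
    config = config or GSNCAConfig()
    if not isinstance(expr, ExpressionMatrix):
        expr = ExpressionMatrix(np.asarray(expr, dtype=float))
    labels = check_labels(labels, expr.n_samples)
    values = expr.values

    if config.check_sd:
        n_bad = _low_sd_count(values, labels, config.min_sd)
        if n_bad:
            raise LowVarianceError(n_bad, "the observed grouping")

    obs, (w1, w2) = _stat_for_labels(values, labels, config.cor_method)

    skipped = 0

    def _guard(perm) -> bool:
        nonlocal skipped
        if config.check_sd and _low_sd_count(values, perm, config.min_sd):
            skipped += 1
            if skipped > config.max_skip:
                raise LowVarianceError(
                    _low_sd_count(values, perm, config.min_sd),
                    f"permuted groupings ({skipped} permutations skipped, "
                    f"max_skip = {config.max_skip})",
                )
            return True
        return False

    perms, is_exh = generate_permutations(labels, nperm, seed=seed, exhaustive=exhaustive)
    if is_exh:
        perm_stats = np.asarray(
            [
                _stat_for_labels(values, perm, config.cor_method)[0]
                for perm in perms
                if not _guard(perm)
            ]
        )
    else:
        redraw = np.random.default_rng(None if seed is None else seed + 1)
        perm_stats = np.empty(nperm, dtype=float)
        for k, perm in enumerate(perms):
            while _guard(perm):
                perm = redraw.permutation(labels)
            perm_stats[k], _ = _stat_for_labels(values, perm, config.cor_method)

    p = perm_pvalue(obs, perm_stats, side="upper")
    return TestResult(
        p_value=p,
        observed_stat=obs,
        perm_stats=perm_stats,
        method="gsnca",
        nperm=perm_stats.shape[0],
        seed=None if is_exh else seed,
        exhaustive=is_exh,
        extras={"weights_group1": w1, "weights_group2": w2, "skipped": skipped},
    )
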