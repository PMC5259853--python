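"""Label-permutation engine and permutation p-value estimators.

Every test in the package estimates significance by permuting the two-group
sample labels while preserving group sizes, then applying the +1/(M+1)
corrected empirical p-value.  When the number of distinct labelings
C(N, n1) does not exceed the requested permutation count, sampling is
replaced by exhaustive enumeration, which removes Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .containers import check_labels

__all__ = ["TestResult", "generate_permutations", "perm_pvalue"]


@dataclass
class TestResult:
    """Outcome of one permutation test.

    Attributes
    ----------
    p_value : float
        Corrected empirical p-value in [1/(M+1), 1].
    observed_stat : float
        Test statistic of the observed labeling.
    perm_stats : ndarray
        Statistic under each of the M permuted labelings.
    method : str
        Test identifier (``ww``, ``ks``, ``md``, ``rks``, ``rmd``,
        ``aggrf``, ``gsnca``).
    nperm : int
        M, the number of permutations actually used.
    seed : int or None
        Seed of the random generator (None in exhaustive mode).
    exhaustive : bool
        True when all C(N, n1) labelings were enumerated.
    extras : dict
        Method-specific diagnostics (e.g. subtree count R, W statistic,
        GSNCA weight vectors, skipped-permutation count).
    """

    __test__ = False  # not a pytest collection target

    p_value: float
    observed_stat: float
    perm_stats: np.ndarray
    method: str
    nperm: int
    seed: int | None
    exhaustive: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.perm_stats = np.asarray(self.perm_stats, dtype=float)
        if self.perm_stats.shape[0] != self.nperm:
            raise ValueError("perm_stats length must equal nperm")
        lo = 1.0 / (self.nperm + 1)
        if not lo <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [{lo}, 1]")


def generate_permutations(labels, nperm: int, seed=None, exhaustive: str = "auto") -> tuple[np.ndarray, bool]:
    """Matrix of permuted label vectors, one row per permutation.

    Parameters
    ----------
    labels : array-like of {1, 2}
        Observed labels; every permutation preserves the group sizes.
    nperm : int
        Requested number of Monte-Carlo permutations, M >= 1.
    seed : int, optional
        Seed for the sampling generator.
    exhaustive : {"auto", "always", "never"}
        In "auto" mode all C(N, n1) distinct labelings are enumerated
        whenever their count is <= nperm.

    Returns
    -------
    perms : ndarray of shape (M, N)
    is_exhaustive : bool
    """
    labels = np.asarray(labels)
    labels = check_labels(labels, labels.shape[0])
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    n = labels.shape[0]
    n1 = int(np.sum(labels == 1))
    n_distinct = comb(n, n1)
    if exhaustive not in ("auto", "always", "never"):
        raise ValueError(f"unknown exhaustive mode {exhaustive!r}")
    do_exhaustive = exhaustive == "always" or (exhaustive == "auto" and n_distinct <= nperm)
    if do_exhaustive:
        perms = np.full((n_distinct, n), 2, dtype=np.int8)
        for row, idx in enumerate(combinations(range(n), n1)):
            perms[row, list(idx)] = 1
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.empty((nperm, n), dtype=np.int8)
    for k in range(nperm):
        perms[k] = rng.permutation(labels)
    return perms, False


def perm_pvalue(obs: float, perms, side: str) -> float:
    """Corrected permutation p-value (#{indicator} + 1) / (M + 1).

    side
        ``lower`` — indicator is perm <= obs (e.g. the runs statistic,
        where few subtrees mean separation);
        ``upper`` — perm >= obs (KS, Fisher T, GSNCA);
        ``two_sided_abs`` — |perm| >= |obs| (the signed MD statistic).

    Distinct labelings can yield analytically identical statistics that
    differ in the last floating-point digit depending on summation order;
    the indicators therefore compare with a relative tolerance of 1e-12 so
    that permutation ties are counted deterministically.
    """
    perms = np.asarray(perms, dtype=float)
    if perms.size == 0:
        raise ValueError("empty permutation sample")
    tol = 1e-12 * max(1.0, abs(obs))
    if side == "lower":
        hits = np.sum(perms <= obs + tol)
    elif side == "upper":
        hits = np.sum(perms >= obs - tol)
    elif side == "two_sided_abs":
        hits = np.sum(np.abs(perms) >= abs(obs) - tol)
    else:
        raise ValueError(f"unknown side {side!r}")
    return float((hits + 1) / (perms.size + 1))
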