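"""Synthetic gene-set generators for the four canonical alternatives.

Two-group multivariate normal gene sets with controllable mean shift
(``delta``), scale change (``sigma_ratio``) and equicorrelation or
planted-hub correlation structure — enough to realize a true null and the
shift, scale and differential-correlation alternatives that the tests in
this package target — plus a crude negative-binomial count generator whose
structurally zero genes exercise the GSNCA standard-deviation guards.

These generators emulate the statistical structure of normalized expression
data, not its full complexity: no library-size effects, no dispersion
trends, no heavy tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "equicorrelation",
    "hub_correlation",
    "simulate_mvn",
    "simulate_hub_correlation",
    "simulate_counts_with_zeros",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Two-group multivariate normal recipe.

    Group 1 ~ N(0, Sigma(rho1)); group 2 ~ N(delta * 1, sigma_ratio^2 *
    Sigma(rho2)), where Sigma(rho) is the p x p equicorrelation matrix.
    ``delta = 0``, ``sigma_ratio = 1`` and ``rho1 == rho2`` give a true
    null: both groups share one distribution.
    """

    p: int = 20
    n1: int = 20
    n2: int = 20
    delta: float = 0.0
    sigma_ratio: float = 1.0
    rho1: float = 0.0
    rho2: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.p < 2:
            raise ValueError("need p >= 2 genes")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        if self.sigma_ratio <= 0:
            raise ValueError("sigma_ratio must be > 0")

    @property
    def is_null(self) -> bool:
        return self.delta == 0.0 and self.sigma_ratio == 1.0 and self.rho1 == self.rho2


def equicorrelation(p: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix (1 - rho) I + rho J; PD iff -1/(p-1) < rho < 1."""
    if not -1.0 / (p - 1) < rho < 1.0:
        raise ValueError(
            f"equicorrelation with rho={rho} is not positive definite for p={p} "
            f"(need -1/(p-1) = {-1.0 / (p - 1):.4f} < rho < 1)"
        )
    return (1.0 - rho) * np.eye(p) + rho * np.ones((p, p))


def hub_correlation(p: int, r_hub: float, r_background: float, which_hub: int = 0) -> np.ndarray:
    """Correlation matrix with one gene at r_hub to all others, rest at r_background.

    Positive definiteness is verified by Cholesky; a non-PD request (e.g.
    r_hub too large relative to r_background) raises.
    """
    if not 0 <= which_hub < p:
        raise ValueError(f"which_hub must index a gene in 0..{p - 1}")
    c = np.full((p, p), float(r_background))
    c[which_hub, :] = r_hub
    c[:, which_hub] = r_hub
    np.fill_diagonal(c, 1.0)
    try:
        np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"correlation matrix (r_hub={r_hub}, r_background={r_background}, p={p}) "
            "is not positive definite"
        ) from None
    return c


def _draw_mvn(rng, mean, cov, n) -> np.ndarray:
    """n draws of a p-variate normal, returned genes x samples."""
    return rng.multivariate_normal(mean, cov, size=n, method="cholesky").T


def simulate_mvn(config: SyntheticConfig):
    """Draw a two-group MVN gene set per the config.

    Returns (ExpressionMatrix, labels): group 1 occupies the first n1
    columns with labels 1, group 2 the remaining n2 with labels 2.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.p
    cov1 = equicorrelation(p, config.rho1)
    cov2 = config.sigma_ratio**2 * equicorrelation(p, config.rho2)
    x = _draw_mvn(rng, np.zeros(p), cov1, config.n1)
    y = _draw_mvn(rng, np.full(p, config.delta), cov2, config.n2)
    labels = np.r_[np.ones(config.n1, dtype=int), np.full(config.n2, 2, dtype=int)]
    return ExpressionMatrix(np.hstack([x, y])), labels


def simulate_hub_correlation(
    p: int,
    r_hub: float,
    r_background: float,
    which_hub: int = 0,
    n: int = 30,
    seed=None,
) -> ExpressionMatrix:
    """One-condition MVN sample with a planted hub gene in the correlation matrix."""
    cov = hub_correlation(p, r_hub, r_background, which_hub)
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(_draw_mvn(rng, np.zeros(p), cov, n))


def simulate_counts_with_zeros(
    p: int,
    n1: int,
    n2: int,
    zero_genes: int = 0,
    seed=None,
    nb_mean: float = 50.0,
    nb_dispersion: float = 5.0,
):
    """Count-like data with structurally silent genes.

    Negative-binomial draws (mean ``nb_mean``, shape ``nb_dispersion``)
    emulating normalized counts; the first ``zero_genes`` genes are set to
    zero in all group-1 samples, producing the zero/tiny standard deviations
    that trip the GSNCA ``min_sd`` guard on the observed grouping and force
    permutation skips.  Returns (ExpressionMatrix, labels).
    """
    if zero_genes > p:
        raise ValueError("zero_genes cannot exceed p")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    # NB via gamma-Poisson mixture
    lam = rng.gamma(shape=nb_dispersion, scale=nb_mean / nb_dispersion, size=(p, n))
    counts = rng.poisson(lam).astype(float)
    counts[:zero_genes, :n1] = 0.0
    labels = np.r_[np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]
    return ExpressionMatrix(counts), labels
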