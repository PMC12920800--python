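"""PCA scores, loadings, and variance accounting via either decomposition path.

The fitted model satisfies, by construction, the identities that the grid
module later re-checks on arbitrary outputs: the sample variance of the k-th
score column equals the k-th covariance eigenvalue, the score standard
deviations are sqrt(lambda), and the variance-explained fractions are
lambda_k / sum(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CenteredMatrix,
    InputError,
    eigen_from_singular,
    eigendecompose,
    sample_covariance,
    singular_from_eigen,
    svd_thin,
)

__all__ = ["PCAModel", "fit_pca", "variance_explained", "score_variance"]


@dataclass(frozen=True)
class PCAModel:
    """Loadings, eigenvalues, singular values, scores and variance shares."""

    loadings: np.ndarray        # m x r, eigenvector columns (canonical signs)
    eigenvalues: np.ndarray     # r, descending
    singular_values: np.ndarray  # r, descending
    scores: np.ndarray          # n x r, Z = Y V
    score_sd: np.ndarray        # sqrt(eigenvalues)
    var_explained: np.ndarray   # fractions summing to 1 (all zero if Y = 0)
    n: int
    m: int
    method: str
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()


def fit_pca(Y: CenteredMatrix, method: str = "svd") -> PCAModel:
    """Fit a PCA on a centred matrix via ``svd`` (default) or ``eigen``.

    Both methods return identical models up to machine precision after sign
    canonicalisation; the eigen path exists for pedagogy (the classical
    variance-maximisation derivation) and for dialect parity.
    """
    if method not in ("svd", "eigen"):
        raise InputError(f"unknown method {method!r}; use 'svd' or 'eigen'")
    n, m = Y.n, Y.m
    if m < 1 or n < 2:
        raise InputError("need n >= 2 observations and m >= 1 features")

    if method == "svd":
        dec = svd_thin(Y)
        V = dec.V
        ell = dec.singular_values
        lam = eigen_from_singular(ell, n)
    else:
        S = sample_covariance(Y, n - 1)
        eig = eigendecompose(S)
        V = eig.eigenvectors
        lam = np.clip(eig.eigenvalues, 0.0, None)
        ell = singular_from_eigen(lam, n)

    Z = Y.values @ V
    total = lam.sum()
    var_explained = lam / total if total > 0 else np.zeros_like(lam)
    return PCAModel(
        loadings=V,
        eigenvalues=lam,
        singular_values=ell,
        scores=Z,
        score_sd=np.sqrt(lam),
        var_explained=var_explained,
        n=n,
        m=m,
        method=method,
        row_labels=Y.row_labels,
        col_labels=Y.col_labels,
    )


def variance_explained(model: PCAModel, k: int) -> float:
    """Cumulative fraction of variance carried by the first k components."""
    r = model.eigenvalues.shape[0]
    if not 1 <= k <= r:
        raise InputError(f"k must be in [1, {r}], got {k}")
    return float(model.var_explained[:k].sum())


def score_variance(model: PCAModel, k: int) -> float:
    """Sample variance (divisor n-1) of score column k (1-based)."""
    r = model.scores.shape[1]
    if not 1 <= k <= r:
        raise InputError(f"k must be in [1, {r}], got {k}")
    return float(model.scores[:, k - 1].var(ddof=1))
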