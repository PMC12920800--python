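"""The alpha-parametrised factorisation Y = A B' and PC-biplot coordinates.

A biplot replaces the diagonal matrix D of the SVD with D^alpha D^(1-alpha),
splitting it between observation coordinates A = U D^alpha and feature
coordinates B = V D^(1-alpha).  The two ends of the parameter range are the
cases practitioners actually use:

* ``alpha = 0`` -- the *PC biplot*: A = U, B = V D.  Feature-vector lengths
  are proportional to feature standard deviations, feature-vector cosines
  equal feature correlations (at full rank), and inter-observation distances
  are proportional to Mahalanobis distances.
* ``alpha = 1`` -- the *scores-and-loadings* overlay: A = Z, B = V.  Still a
  biplot, but none of the PC-biplot geometric identities is guaranteed.

Truncating to the k largest singular values makes A B' the best rank-k
approximation of Y (Eckart-Young).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CenteredMatrix, InputError, svd_thin

__all__ = [
    "BiplotConfig",
    "BiplotCoordinates",
    "factorise",
    "pc_biplot",
    "scores_loadings_biplot",
    "render",
]


@dataclass(frozen=True)
class BiplotConfig:
    alpha: float
    rank: int

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.rank < 1:
            raise InputError("rank must be >= 1")


@dataclass(frozen=True)
class BiplotCoordinates:
    A: np.ndarray                 # n x k observation coordinates
    B: np.ndarray                 # m x k feature coordinates
    config: BiplotConfig
    reconstruction_error: float   # Frobenius norm of Y - A B'
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    @property
    def rank(self) -> int:
        return self.config.rank


def factorise(Y: CenteredMatrix, config: BiplotConfig) -> BiplotCoordinates:
    """Split ``Y = U D^alpha D^(1-alpha) V'`` into A (n x k) and B (m x k).

    Truncation keeps the k largest singular values (ties broken by original
    order).  At full rank A B' reconstructs Y exactly for every alpha.
    """
    dec = svd_thin(Y)
    if config.rank > dec.r:
        raise InputError(
            f"rank {config.rank} exceeds min(n, m) = {dec.r}"
        )
    k = config.rank
    ell = dec.singular_values[:k]
    # 0**0 == 1 by numpy convention, so alpha = 0 leaves A = U even for a
    # zero singular value.
    A = dec.U[:, :k] * np.power(ell, config.alpha)
    B = dec.V[:, :k] * np.power(ell, 1.0 - config.alpha)
    err = float(np.linalg.norm(Y.values - A @ B.T))
    return BiplotCoordinates(
        A=A,
        B=B,
        config=config,
        reconstruction_error=err,
        row_labels=Y.row_labels,
        col_labels=Y.col_labels,
    )


def pc_biplot(Y: CenteredMatrix, k: int) -> BiplotCoordinates:
    """PC biplot (alpha = 0): A = U, B' = D V'; verifies A = Z D^-1.

    Raises if a retained singular value is zero (the A = Z D^-1 route would
    divide by zero).
    """
    dec = svd_thin(Y)
    if k > dec.r:
        raise InputError(f"rank {k} exceeds min(n, m) = {dec.r}")
    ell = dec.singular_values[:k]
    # null components: numerically zero relative to the leading singular value
    tiny = 1e-12 * max(dec.singular_values[0], 0.0)
    if np.any(ell <= tiny):
        raise InputError("zero singular value within the first k components")
    coords = factorise(Y, BiplotConfig(alpha=0.0, rank=k))
    # Internal consistency with the score route (Z D^-1 = U D D^-1 = U).
    Z = Y.values @ dec.V[:, :k]
    dev = np.abs(coords.A - Z / ell).max()
    scale = max(np.abs(coords.A).max(), 1.0)
    if dev > 1e-10 * scale:
        raise AssertionError(
            f"A = Z D^-1 self-check failed (max dev {dev:.3e})"
        )
    return coords


def scores_loadings_biplot(Y: CenteredMatrix, k: int) -> BiplotCoordinates:
    """Scores-and-loadings overlay (alpha = 1): A = Z truncated, B = V truncated."""
    return factorise(Y, BiplotConfig(alpha=1.0, rank=k))


def render(coords: BiplotCoordinates, out_path) -> None:
    """Write a two-dimensional biplot: points for observations, arrows for features.

    Feature arrows are drawn against secondary axes whose scale is the ratio
    of max-abs extents of B over A — purely cosmetic; stored coordinates are
    never rescaled.
    """
    if coords.A.shape[1] != 2 or coords.B.shape[1] != 2:
        raise InputError("render requires rank-2 coordinates")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    A, B = coords.A, coords.B
    ax.scatter(A[:, 0], A[:, 1], color="tab:blue", zorder=3)
    for i, lab in enumerate(coords.row_labels or map(str, range(len(A)))):
        ax.annotate(lab, A[i], textcoords="offset points", xytext=(4, 4))

    a_ext = max(np.abs(A).max(), 1e-12)
    b_ext = max(np.abs(B).max(), 1e-12)
    scale = a_ext / b_ext
    for j, lab in enumerate(coords.col_labels or map(str, range(len(B)))):
        ax.annotate(
            "",
            xy=(B[j, 0] * scale, B[j, 1] * scale),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="purple"),
        )
        ax.annotate(lab, (B[j, 0] * scale, B[j, 1] * scale), color="purple")

    sec_x = ax.secondary_xaxis("top", functions=(lambda v: v / scale, lambda v: v * scale))
    sec_y = ax.secondary_yaxis("right", functions=(lambda v: v / scale, lambda v: v * scale))
    sec_x.set_xlabel("feature scale, dim 1")
    sec_y.set_ylabel("feature scale, dim 2")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
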