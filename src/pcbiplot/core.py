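"""Centring, covariance, and the two matrix-decomposition routes behind PCA.

PCA can be reached either by eigendecomposing the sample covariance matrix
``S = Y'Y/(n-1)`` of a column-centred data matrix ``Y`` (the classical,
variance-maximising derivation) or by taking the thin singular value
decomposition ``Y = U D V'`` directly.  The two routes agree: the right
singular vectors are the covariance eigenvectors up to column signs, and the
singular values relate to the eigenvalues through

    ell_k = sqrt(n - 1) * sqrt(lambda_k)

Implementations frequently blur this relationship (dividing by ``n`` instead
of ``n - 1``, or conflating singular values with score standard deviations),
which is why this module keeps both routes explicit and pins down a
deterministic ordering and sign convention.

Sign convention: eigenvectors and right singular vectors are only determined
up to a sign per column.  We canonicalise so that in each column the entry of
largest absolute value is positive (ties broken by lowest row index), and any
paired matrix (``U``, scores) is co-flipped so products are unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputError",
    "LabeledMatrix",
    "CenteredMatrix",
    "CovarianceMatrix",
    "EigenSystem",
    "SVDSystem",
    "center",
    "unitise",
    "sample_covariance",
    "eigendecompose",
    "svd_thin",
    "eigen_from_singular",
    "singular_from_eigen",
    "sign_canonicalise",
]

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Raised when user-supplied data violates a precondition."""


def _check_labels(labels, n: int, what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise InputError(f"{what} labels: expected {n}, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate {what} labels")
    return labels


@dataclass(frozen=True)
class LabeledMatrix:
    """An observations-by-features numeric matrix with row and column labels."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InputError("matrix must be 2-dimensional")
        n, m = values.shape
        if n < 2:
            raise InputError(f"need at least 2 observations, got {n}")
        if m < 1:
            raise InputError("need at least 1 feature")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise InputError(
                f"non-finite entry at row {bad[0]}, column {bad[1]}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "row_labels", _check_labels(self.row_labels, n, "row")
        )
        object.__setattr__(
            self, "col_labels", _check_labels(self.col_labels, m, "column")
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CenteredMatrix(LabeledMatrix):
    """A column-centred matrix together with the subtracted column means."""

    original_means: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        means = np.asarray(self.original_means, dtype=float).reshape(-1)
        if means.shape[0] != self.m:
            raise InputError("original_means length must match column count")
        object.__setattr__(self, "original_means", means)
        scale = np.maximum(np.abs(self.values).max(axis=0), 1.0)
        resid = np.abs(self.values.mean(axis=0))
        if np.any(resid > 1e-12 * scale):
            raise InputError("matrix is not centred to tolerance")


@dataclass(frozen=True)
class CovarianceMatrix:
    """Symmetric m-by-m covariance matrix with its divisor (n-1 or n)."""

    values: np.ndarray
    divisor: int
    n: int
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InputError("covariance matrix must be square")
        scale = max(np.abs(values).max(), 1.0)
        if np.abs(values - values.T).max() > 1e-12 * scale:
            raise InputError("covariance matrix is not symmetric")
        if self.divisor <= 0:
            raise InputError("divisor must be positive")
        smallest = np.linalg.eigvalsh(values)[0]
        if smallest < -1e-10 * scale:
            raise InputError("covariance matrix is not positive semi-definite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EigenSystem:
    """Eigenvalues (descending) and eigenvector columns of a covariance matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float)
        )
        object.__setattr__(
            self, "eigenvectors", np.asarray(self.eigenvectors, dtype=float)
        )


@dataclass(frozen=True)
class SVDSystem:
    """Thin SVD ``Y = U diag(ell) V'`` with descending singular values."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "U", np.asarray(self.U, dtype=float))
        object.__setattr__(
            self,
            "singular_values",
            np.asarray(self.singular_values, dtype=float),
        )
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float))

    @property
    def r(self) -> int:
        return self.singular_values.shape[0]

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.singular_values)


def center(X: LabeledMatrix) -> CenteredMatrix:
    """Subtract each column's mean; sample variances are unchanged."""
    means = X.values.mean(axis=0)
    return CenteredMatrix(
        values=X.values - means,
        row_labels=X.row_labels,
        col_labels=X.col_labels,
        original_means=means,
    )


def unitise(X: LabeledMatrix) -> LabeledMatrix:
    """Min-max rescale every column to the unit interval [0, 1].

    Raises :class:`InputError` naming the offending column if a column is
    constant (zero range).
    """
    lo = X.values.min(axis=0)
    hi = X.values.max(axis=0)
    rng = hi - lo
    degenerate = np.nonzero(rng <= 0)[0]
    if degenerate.size:
        names = ", ".join(X.col_labels[j] for j in degenerate)
        raise InputError(f"constant column(s) cannot be unitised: {names}")
    return LabeledMatrix(
        values=(X.values - lo) / rng,
        row_labels=X.row_labels,
        col_labels=X.col_labels,
    )


def sample_covariance(Y: CenteredMatrix, divisor: int | None = None) -> CovarianceMatrix:
    """``S = Y'Y / divisor``; the reference divisor is ``n - 1``.

    ``divisor`` must be ``n - 1`` (default) or ``n``; the ``n`` variant exists
    because several published implementations use it.
    """
    n = Y.n
    if divisor is None:
        divisor = n - 1
    if divisor <= 0:
        raise InputError("divisor must be positive")
    if divisor not in (n - 1, n):
        raise InputError(f"divisor must be n-1={n - 1} or n={n}, got {divisor}")
    S = Y.values.T @ Y.values / divisor
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding
    return CovarianceMatrix(values=S, divisor=divisor, n=n, col_labels=Y.col_labels)


def sign_canonicalise(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip column signs so each column's largest-|entry| is positive.

    Ties on magnitude are broken by the lowest row index (``argmax`` picks the
    first maximal entry).  Returns the flipped matrix and a vector of +-1
    flips so callers can co-flip a paired matrix (``U`` or scores).  An
    all-zero column gets flip +1 and a logged warning.
    """
    V = np.asarray(V, dtype=float)
    flips = np.ones(V.shape[1])
    for k in range(V.shape[1]):
        col = V[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] == 0.0:
            logger.warning("sign_canonicalise: column %d is all zero", k)
            continue
        if col[i] < 0:
            flips[k] = -1.0
    return V * flips, flips


def eigendecompose(S: CovarianceMatrix) -> EigenSystem:
    """Solve ``(S - lambda I) a = 0``: descending eigenvalues, canonical signs.

    Eigenvalue ties keep the order produced by a stable descending sort.
    """
    vals, vecs = np.linalg.eigh(S.values)
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    vecs, _ = sign_canonicalise(vecs)
    return EigenSystem(eigenvalues=vals, eigenvectors=vecs)


def svd_thin(Y: CenteredMatrix | LabeledMatrix) -> SVDSystem:
    """Thin SVD of the data matrix with canonical column signs on ``V``.

    ``U`` is co-flipped so that ``U diag(ell) V'`` still reconstructs the
    input exactly.
    """
    U, s, Vt = np.linalg.svd(Y.values, full_matrices=False)
    V, flips = sign_canonicalise(Vt.T)
    U = U * flips
    return SVDSystem(U=U, singular_values=s, V=V)


def eigen_from_singular(ell: np.ndarray, n: int) -> np.ndarray:
    """Convert singular values to covariance eigenvalues: ``lambda = ell^2/(n-1)``."""
    ell = np.asarray(ell, dtype=float)
    if n < 2:
        raise InputError("need n >= 2")
    if np.any(ell < 0):
        raise InputError("singular values must be non-negative")
    return ell**2 / (n - 1)


def singular_from_eigen(lam: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`eigen_from_singular`: ``ell = sqrt(n-1) * sqrt(lambda)``."""
    lam = np.asarray(lam, dtype=float)
    if n < 2:
        raise InputError("need n >= 2")
    if np.any(lam < -1e-12 * max(1.0, np.abs(lam).max(initial=0.0))):
        raise InputError("eigenvalues must be non-negative")
    return np.sqrt(n - 1) * np.sqrt(np.clip(lam, 0.0, None))
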