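"""Synthetic data with a controlled population covariance, and negative controls.

The generator draws Gaussian data whose population covariance has a
prescribed spectrum under a seeded random orthogonal rotation.  The
identities exercised by the grid are distribution-free, so a Gaussian
generator suffices for correctness testing; what matters is control over the
spectrum (well-separated, degenerate, or rank-deficient) and bit-for-bit
reproducibility from the seeds.

:func:`corrupt` produces copies of fitted objects with exactly one
documented deviation applied — the flaws the grid is designed to catch — so
each check can be shown to fail on its matched corruption and pass on the
others.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .biplot import BiplotCoordinates
from .core import InputError, LabeledMatrix
from .pca import PCAModel

__all__ = ["SyntheticSpec", "generate", "corrupt", "CORRUPTION_MODES"]


@dataclass(frozen=True)
class SyntheticSpec:
    n: int
    m: int
    spectrum: tuple[float, ...]
    rotation_seed: int = 0
    noise_seed: int = 1
    distribution: str = "gaussian"

    def __post_init__(self):
        spectrum = tuple(float(s) for s in self.spectrum)
        if len(spectrum) != self.m:
            raise InputError("spectrum length must equal m")
        if any(s < 0 for s in spectrum):
            raise InputError("spectrum must be non-negative")
        if self.distribution != "gaussian":
            raise InputError("only the gaussian generator is implemented")
        object.__setattr__(self, "spectrum", spectrum)


def _random_rotation(m: int, seed: int) -> np.ndarray:
    """Haar-ish orthogonal matrix via QR of a seeded Gaussian draw."""
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((m, m)))
    return Q * np.sign(np.diag(R))


def generate(spec: SyntheticSpec) -> LabeledMatrix:
    """Draw n rows with population covariance Q diag(spectrum) Q'.

    ``m > n`` is permitted (it exercises singular-covariance paths) but
    flagged with a warning.
    """
    if spec.m > spec.n:
        warnings.warn(
            f"m={spec.m} > n={spec.n}: sample covariance will be singular",
            stacklevel=2,
        )
    Q = _random_rotation(spec.m, spec.rotation_seed)
    half = Q * np.sqrt(np.asarray(spec.spectrum))  # Q diag(sqrt(s))
    rng = np.random.default_rng(spec.noise_seed)
    X = rng.standard_normal((spec.n, spec.m)) @ half.T
    return LabeledMatrix(
        values=X,
        row_labels=tuple(f"r{i}" for i in range(spec.n)),
        col_labels=tuple(f"f{j}" for j in range(spec.m)),
    )


#: mode -> (target object type, grid check the mode is built to break)
CORRUPTION_MODES = {
    "divisor_n": ("PCAModel", "I.D"),
    "swap_singular": ("PCAModel", "II.D"),
    "scale_loadings": ("PCAModel", "VI.B"),
    "scale_A": ("BiplotCoordinates", "III.A"),
    "scale_B": ("BiplotCoordinates", "V.A"),
    "permute_rows": ("CenteredMatrix", "VII.A"),
    "flip_column": ("either", "sign_flip"),
}


def corrupt(obj, mode: str):
    """Return a copy of a model or coordinate set with one documented flaw.

    * ``divisor_n``    — eigenvalues rescaled by (n-1)/n, as if the covariance
      divisor had been n (breaks I.D).
    * ``swap_singular`` — singular values replaced by sqrt(lambda), the common
      conflation of singular values with score standard deviations (breaks II.D).
    * ``scale_loadings`` — loading columns multiplied by sqrt(lambda), the
      implicit normalisation some implementations apply (breaks VI.B).
    * ``scale_A``      — observation coordinates multiplied by sqrt(n-1), the
      alternative scaling some references adopt (breaks III.A, and with it
      the distance property VII.A — the scaling changes which Mahalanobis
      statement holds).
    * ``scale_B``      — feature coordinates doubled (breaks V.A; cosines are
      scale-invariant so VI.A survives).
    * ``permute_rows`` — rows of the data matrix reversed while coordinates
      keep their order; every per-column statistic survives but the
      observation pairing behind the distance identity VII.A breaks.
    * ``flip_column``  — first column of the scores / A negated (sign_flip, not
      fail, in sign-aware checks).
    """
    if mode not in CORRUPTION_MODES:
        raise InputError(
            f"unknown corruption mode {mode!r}; known: {sorted(CORRUPTION_MODES)}"
        )
    if isinstance(obj, PCAModel):
        if mode == "divisor_n":
            lam = obj.eigenvalues * (obj.n - 1) / obj.n
            return dataclasses.replace(
                obj, eigenvalues=lam, score_sd=np.sqrt(lam)
            )
        if mode == "swap_singular":
            return dataclasses.replace(
                obj, singular_values=np.sqrt(obj.eigenvalues)
            )
        if mode == "scale_loadings":
            V = obj.loadings * np.sqrt(np.clip(obj.eigenvalues, 0.0, None))
            return dataclasses.replace(obj, loadings=V)
        if mode == "flip_column":
            scores = obj.scores.copy()
            scores[:, 0] = -scores[:, 0]
            return dataclasses.replace(obj, scores=scores)
        raise InputError(f"mode {mode!r} does not apply to a PCAModel")
    if isinstance(obj, BiplotCoordinates):
        if mode == "scale_A":
            A = obj.A * np.sqrt(len(obj.A) - 1)
            return dataclasses.replace(obj, A=A)
        if mode == "scale_B":
            return dataclasses.replace(obj, B=obj.B * 2.0)
        if mode == "flip_column":
            A = obj.A.copy()
            A[:, 0] = -A[:, 0]
            return dataclasses.replace(obj, A=A)
        raise InputError(f"mode {mode!r} does not apply to BiplotCoordinates")
    if isinstance(obj, LabeledMatrix):  # includes CenteredMatrix
        if mode == "permute_rows":
            return dataclasses.replace(
                obj,
                values=obj.values[::-1].copy(),
                row_labels=tuple(reversed(obj.row_labels)),
            )
        raise InputError(f"mode {mode!r} does not apply to a data matrix")
    raise InputError(f"cannot corrupt object of type {type(obj).__name__}")
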