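"""Packaged worked-example datasets.

Two small matrices are shipped verbatim as printed (2 decimal places):

* ``toy_table2`` — a fictitious 6 x 2 example used to exercise every
  building block by hand.
* ``ctsc_table7`` — an 11 x 4 excerpt of desensitised clinical-trial
  supply-chain data (stockout events, patients enrolled, clinics, trial
  duration in months), already unitised to [0, 1] per column.

Each fixture carries a dictionary of the reference values printed alongside
the data (eigenvalues, loadings magnitudes, score magnitudes, cosines,
p-values, ...) so tests can compare computed output against the printed
record at the printed rounding (+-0.01; +-0.0005 for p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InputError, LabeledMatrix

__all__ = ["Fixture", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("toy_table2", "ctsc_table7")


@dataclass(frozen=True)
class Fixture:
    name: str
    matrix: LabeledMatrix
    expected: dict


_TOY_ROWS = ["A", "B", "C", "D", "E", "F"]
_TOY_X = np.array(
    [
        [10.0, 6.0],
        [11.0, 4.0],
        [8.0, 5.0],
        [3.0, 3.0],
        [2.0, 2.8],
        [1.0, 1.0],
    ]
)

_TOY_EXPECTED = {
    "means": np.array([5.83, 3.63]),
    "sample_var": np.array([18.97, 3.13]),
    "centred_row_A": np.array([4.17, 2.37]),
    "eigenvalues": np.array([21.28, 0.81]),
    "abs_loadings": np.array([[0.94, 0.34], [0.34, 0.94]]),
    "abs_scores_pc1": np.array([4.72, 4.99, 2.50, 2.88, 3.89, 5.44]),
    "abs_scores_pc2": np.array([0.83, 1.39, 0.56, 0.36, 0.50, 0.85]),
    "score_var": np.array([21.29, 0.81]),
    "pc1_proj_coords": np.array(
        [
            [4.44, 1.59],
            [4.70, 1.68],
            [2.35, 0.84],
            [-2.71, -0.97],
            [-3.66, -1.31],
            [-5.12, -1.83],
        ]
    ),
    "cos_theta_12": 0.84,
    "pc1_var_share": 0.96,
}

_CTSC_ROWS = list("ABCDEFGHIJK")
_CTSC_COLS = ["STO", "ENR", "CLI", "DUR"]
_CTSC_X = np.array(
    [
        [0.12, 0.23, 0.10, 1.00],
        [0.00, 0.00, 0.00, 0.23],
        [0.65, 0.49, 0.24, 0.71],
        [0.29, 0.48, 0.26, 0.71],
        [0.00, 0.30, 0.32, 0.14],
        [1.00, 1.00, 1.00, 0.16],
        [0.35, 0.83, 0.26, 0.58],
        [0.06, 0.05, 0.04, 0.41],
        [0.00, 0.53, 0.26, 0.14],
        [0.06, 0.30, 0.43, 0.14],
        [0.00, 0.20, 0.30, 0.00],
    ]
)

_CTSC_EXPECTED = {
    "means": np.array([0.23, 0.40, 0.29, 0.38]),
    "sample_var": np.array([0.11, 0.09, 0.07, 0.10]),
    "eigenvalues": np.array([0.23, 0.12, 0.02, 0.01]),
    "singular_values": np.array([1.51, 1.09, 0.46, 0.29]),
    "abs_loadings_pc1": np.array([0.64, 0.60, 0.49, 0.01]),
    "loadings": np.array(
        [
            [0.64, 0.20, -0.62, 0.41],
            [0.60, 0.03, 0.77, 0.22],
            [0.49, -0.31, -0.14, -0.80],
            [0.01, 0.93, 0.07, -0.37],
        ]
    ),
    # PC-biplot feature coordinates B (alpha = 0), first two components
    "B_rank2": np.array(
        [
            [0.96, 0.22],
            [0.91, 0.03],
            [0.74, -0.34],
            [0.02, 1.01],
        ]
    ),
    "b_norm_rank2": np.array([0.99, 0.91, 0.81, 1.01]),
    "b_norm_full": np.array([1.03, 0.98, 0.85, 1.02]),
    "feature_sd": np.array([0.33, 0.31, 0.27, 0.32]),
    "corr_with_pcs": np.array(
        [
            [0.93, 0.21, -0.28, 0.11],
            [0.93, 0.03, 0.36, 0.07],
            [0.87, -0.40, -0.07, -0.27],
            [0.02, 0.99, 0.03, -0.10],
        ]
    ),
    "abs_score_F_pc1": 1.19,
    "scores": np.array(
        [
            [-0.26, 0.60, 0.00, -0.15],
            [-0.53, -0.11, -0.14, 0.11],
            [0.30, 0.41, -0.16, 0.11],
            [0.07, 0.33, 0.05, -0.05],
            [-0.20, -0.28, 0.04, -0.05],
            [1.19, -0.26, -0.13, -0.04],
            [0.33, 0.23, 0.27, 0.10],
            [-0.44, 0.06, -0.13, 0.05],
            [-0.08, -0.26, 0.23, 0.05],
            [-0.11, -0.30, -0.01, -0.12],
            [-0.27, -0.41, -0.04, -0.00],
        ]
    ),
    "biplot_U_rank2": np.array(
        [
            [-0.17, 0.56],
            [-0.35, -0.10],
            [0.20, 0.37],
            [0.05, 0.30],
            [-0.13, -0.26],
            [0.79, -0.24],
            [0.22, 0.21],
            [-0.29, 0.05],
            [-0.05, -0.24],
            [-0.07, -0.28],
            [-0.18, -0.38],
        ]
    ),
    "score_var": np.array([0.23, 0.12, 0.02, 0.01]),
    "two_pc_var_share_min": 0.92,
    # feature pair -> (cos rank-2, cos all PCs, correlation, p-value)
    "pairs": {
        ("STO", "ENR"): (0.98, 0.78, 0.78, 0.0048),
        ("STO", "CLI"): (0.79, 0.72, 0.72, 0.0132),
        ("STO", "DUR"): (0.24, 0.20, 0.20, 0.5481),
        ("ENR", "CLI"): (0.89, 0.75, 0.75, 0.0074),
        ("ENR", "DUR"): (0.05, 0.05, 0.05, 0.8885),
        ("CLI", "DUR"): (-0.40, -0.36, -0.36, 0.2770),
    },
}


def load_fixture(name: str) -> Fixture:
    """Return a packaged fixture by name (``toy_table2`` or ``ctsc_table7``)."""
    if name == "toy_table2":
        matrix = LabeledMatrix(
            values=_TOY_X,
            row_labels=tuple(_TOY_ROWS),
            col_labels=("Feat1", "Feat2"),
        )
        return Fixture(name=name, matrix=matrix, expected=dict(_TOY_EXPECTED))
    if name == "ctsc_table7":
        matrix = LabeledMatrix(
            values=_CTSC_X,
            row_labels=tuple(_CTSC_ROWS),
            col_labels=tuple(_CTSC_COLS),
        )
        return Fixture(name=name, matrix=matrix, expected=dict(_CTSC_EXPECTED))
    raise InputError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
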