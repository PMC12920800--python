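import numpy as np
import pytest

import pcbiplot as pb


@pytest.fixture(scope="session")
def toy():
    return pb.load_fixture("toy_table2")


@pytest.fixture(scope="session")
def ctsc():
    return pb.load_fixture("ctsc_table7")


@pytest.fixture(scope="session")
def toy_Y(toy):
    return pb.center(toy.matrix)


@pytest.fixture(scope="session")
def ctsc_Y(ctsc):
    return pb.center(ctsc.matrix)


def random_matrix(seed: int, n: int | None = None, m: int | None = None) -> pb.LabeledMatrix:
    """Well-conditioned random data for identity testing."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(8, 40))   # n >= m + 2 keeps Y full column rank
    m = m or int(rng.integers(2, 7))
    spectrum = np.sort(rng.uniform(0.5, 8.0, size=m))[::-1]
    spec = pb.SyntheticSpec(
        n=n, m=m, spectrum=tuple(spectrum),
        rotation_seed=seed * 2 + 1, noise_seed=seed * 2 + 2,
    )
    return pb.generate(spec)


def check_battery(Y, S, model, coords):
    """All grid checks wired the way run_grid wires them, with injectable parts.

    II.D's eigensystem comes from S independently, so corruptions of the
    model reach only the checks that consume the corrupted artifact.
    """
    from pcbiplot import grid as g
    from pcbiplot.core import SVDSystem

    svd_sys = SVDSystem(
        U=model.scores / np.linalg.norm(model.scores, axis=0),
        singular_values=model.singular_values,
        V=model.loadings,
    )
    eig_sys = pb.eigendecompose(S)
    return {
        o.check_id: o.status
        for o in [
            g.check_score_variance(model),
            g.check_singular_eigen(svd_sys, eig_sys, Y.n),
            g.check_observation_coords(coords, model),
            g.check_feature_sd(coords, S),
            g.check_cosine_correlation(coords, Y)[0],
            g.check_feature_score_corr(model, S),
            g.check_mahalanobis(coords, Y, S)[0],
        ]
    }


def brute_force_top_eig(S: np.ndarray, n_grid: int = 10**6):
    """Grid-search oracle for the leading eigenpair of a 2x2 covariance.

    Maximises a'Sa over unit vectors a = (cos phi, sin phi); independent of
    any eigensolver.
    """
    phi = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    c, s = np.cos(phi), np.sin(phi)
    val = S[0, 0] * c**2 + 2 * S[0, 1] * c * s + S[1, 1] * s**2
    i = int(np.argmax(val))
    return float(val[i]), float(phi[i])
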