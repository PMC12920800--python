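import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcbiplot as pb
from pcbiplot import grid as g

from conftest import check_battery as battery
from conftest import random_matrix


@pytest.fixture(scope="module")
def parts():
    X = random_matrix(77, n=25, m=4)
    Y = pb.center(X)
    S = pb.sample_covariance(Y)
    model = pb.fit_pca(Y)
    coords = pb.pc_biplot(Y, 4)
    return Y, S, model, coords


class TestScoreVariance:
    def test_exact_on_fixture(self, toy_Y):
        out = g.check_score_variance(pb.fit_pca(toy_Y))
        assert out.status == "exact"

    def test_fails_when_singular_values_masquerade_as_eigenvalues(self, toy_Y):
        import dataclasses

        model = pb.fit_pca(toy_Y)
        conflated = dataclasses.replace(model, eigenvalues=model.singular_values)
        assert g.check_score_variance(conflated).status == "fail"

    def test_zero_variance_column_still_exact(self):
        rng = np.random.default_rng(0)
        values = np.column_stack([rng.normal(size=10), np.full(10, 3.0)])
        Y = pb.center(
            pb.LabeledMatrix(values, tuple(f"r{i}" for i in range(10)), ("a", "b"))
        )
        assert g.check_score_variance(pb.fit_pca(Y)).status == "exact"


class TestSingularEigen:
    def test_exact_on_ctsc(self, ctsc_Y):
        dec = pb.svd_thin(ctsc_Y)
        eig = pb.eigendecompose(pb.sample_covariance(ctsc_Y))
        assert g.check_singular_eigen(dec, eig, ctsc_Y.n).status == "exact"

    def test_divisor_n_convention_fails(self, ctsc_Y):
        """The sqrt(n)-for-sqrt(n-1) substitution breaks the relationship."""
        dec = pb.svd_thin(ctsc_Y)
        eig_n = pb.eigendecompose(pb.sample_covariance(ctsc_Y, ctsc_Y.n))
        assert g.check_singular_eigen(dec, eig_n, ctsc_Y.n).status == "fail"

    def test_degenerate_n_two(self):
        Y = pb.center(pb.LabeledMatrix([[0.0, 1.0], [2.0, 5.0]], ("a", "b"), ("x", "y")))
        dec = pb.svd_thin(Y)
        eig = pb.eigendecompose(pb.sample_covariance(Y))
        assert g.check_singular_eigen(dec, eig, 2).status == "exact"


class TestObservationCoords:
    def test_self_consistency(self, parts):
        Y, S, model, coords = parts
        assert g.check_observation_coords(coords, model).status == "exact"

    def test_printed_scores_over_singular_value_give_U(self, ctsc, ctsc_Y):
        # oracle: elementwise division of the printed score column by ell_1
        ell1 = pb.svd_thin(ctsc_Y).singular_values[0]
        u1 = ctsc.expected["scores"][:, 0] / ell1
        np.testing.assert_allclose(
            np.abs(u1), np.abs(ctsc.expected["biplot_U_rank2"][:, 0]), atol=0.02
        )

    def test_jolliffe_alternative_scaling_fails(self, parts):
        Y, S, model, coords = parts
        scaled = pb.corrupt(coords, "scale_A")
        assert g.check_observation_coords(scaled, model).status == "fail"

    def test_flipped_column_is_sign_flip_not_fail(self, parts):
        Y, S, model, coords = parts
        flipped = pb.corrupt(coords, "flip_column")
        assert g.check_observation_coords(flipped, model).status == "sign_flip"


class TestFeatureSd:
    def test_full_rank_exact_ctsc(self, ctsc_Y):
        S = pb.sample_covariance(ctsc_Y)
        coords = pb.pc_biplot(ctsc_Y, 4)
        out = g.check_feature_sd(coords, S)
        assert out.status == "exact"

    def test_printed_norm_matches_sigma(self, ctsc, ctsc_Y):
        coords = pb.pc_biplot(ctsc_Y, 4)
        j = list(ctsc.matrix.col_labels).index("STO")
        assert np.linalg.norm(coords.B[j]) / np.sqrt(10) == pytest.approx(
            0.33, abs=0.01
        )

    def test_rank_two_is_approximation_not_failure(self, ctsc_Y):
        S = pb.sample_covariance(ctsc_Y)
        out = g.check_feature_sd(pb.pc_biplot(ctsc_Y, 2), S)
        assert out.status == "skipped"
        assert "approximation" in out.detail

    def test_alpha_one_violates_identity(self, ctsc_Y):
        S = pb.sample_covariance(ctsc_Y)
        out = g.check_feature_sd(pb.scores_loadings_biplot(ctsc_Y, 4), S)
        assert out.status == "fail"


class TestCosineCorrelation:
    def test_toy_pair(self, toy_Y):
        coords = pb.pc_biplot(toy_Y, 2)
        out, pairs = g.check_cosine_correlation(coords, toy_Y)
        assert out.status == "exact"
        assert pairs[0].cos_full == pytest.approx(0.84, abs=0.01)
        assert pairs[0].pearson_r == pytest.approx(0.84, abs=0.01)

    def test_ctsc_sto_enr_pair(self, ctsc_Y):
        coords = pb.pc_biplot(ctsc_Y, 4)
        out, pairs = g.check_cosine_correlation(coords, ctsc_Y)
        pair = next(p for p in pairs if {p.feature_a, p.feature_b} == {"STO", "ENR"})
        assert pair.cos_full == pytest.approx(0.78, abs=0.01)
        assert pair.pearson_r == pytest.approx(0.78, abs=0.01)
        assert pair.cos_rank2 == pytest.approx(0.98, abs=0.01)

    def test_orthogonal_features_give_zero_cosine(self):
        values = np.array(
            [[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]
        )  # exactly uncorrelated columns
        Y = pb.center(pb.LabeledMatrix(values, tuple("abcd"), ("x", "y")))
        coords = pb.pc_biplot(Y, 2)
        out, pairs = g.check_cosine_correlation(coords, Y)
        assert abs(pairs[0].cos_full) < 1e-10
        assert out.status == "exact"

    def test_printed_p_value_reproduced(self, ctsc_Y):
        coords = pb.pc_biplot(ctsc_Y, 4)
        _, pairs = g.check_cosine_correlation(coords, ctsc_Y)
        pair = next(p for p in pairs if {p.feature_a, p.feature_b} == {"STO", "ENR"})
        assert pair.p_value == pytest.approx(0.0048, abs=0.0005)


class TestFeatureScoreCorr:
    def test_printed_correlations(self, ctsc, ctsc_Y):
        model = pb.fit_pca(ctsc_Y)
        S = pb.sample_covariance(ctsc_Y)
        assert g.check_feature_score_corr(model, S).status == "exact"
        # corr(z_1, STO) = 0.93 and corr(z_2, DUR) = 0.99 as printed
        sto = list(ctsc.matrix.col_labels).index("STO")
        dur = list(ctsc.matrix.col_labels).index("DUR")
        r1 = np.corrcoef(model.scores[:, 0], ctsc_Y.values[:, sto])[0, 1]
        r2 = np.corrcoef(model.scores[:, 1], ctsc_Y.values[:, dur])[0, 1]
        assert abs(r1) == pytest.approx(0.93, abs=0.01)
        assert abs(r2) == pytest.approx(0.99, abs=0.01)

    def test_scaled_loadings_fail(self, parts):
        Y, S, model, coords = parts
        assert (
            g.check_feature_score_corr(pb.corrupt(model, "scale_loadings"), S).status
            == "fail"
        )


class TestMahalanobis:
    def test_toy_pair_against_brute_force(self, toy_Y):
        """Explicit 2x2 inverse quadratic form vs (n-1) d^2 for pair (A, B)."""
        S = pb.sample_covariance(toy_Y).values
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        d = toy_Y.values[0] - toy_Y.values[1]
        lhs = float(d @ Sinv @ d)
        coords = pb.pc_biplot(toy_Y, 2)
        rhs = 5 * float(((coords.A[0] - coords.A[1]) ** 2).sum())
        assert lhs == pytest.approx(rhs, abs=1e-10 * max(lhs, 1.0))

    def test_same_row_distance_is_zero(self, ctsc_Y):
        S = pb.sample_covariance(ctsc_Y)
        coords = pb.pc_biplot(ctsc_Y, 4)
        out, pairs = g.check_mahalanobis(coords, ctsc_Y, S)
        assert out.status == "exact"
        assert all(p.mahalanobis_sq > 0 for p in pairs)

    def test_rank_two_reports_approximation(self, ctsc_Y):
        S = pb.sample_covariance(ctsc_Y)
        out, _ = g.check_mahalanobis(pb.pc_biplot(ctsc_Y, 2), ctsc_Y, S)
        assert out.status == "skipped"
        assert "approximation" in out.detail

    @pytest.mark.filterwarnings("ignore:m=5 > n=3")
    def test_singular_covariance_skipped(self):
        X = random_matrix(9, n=3, m=5)
        Y = pb.center(X)
        S = pb.sample_covariance(Y)
        dec = pb.svd_thin(Y)
        coords = pb.pc_biplot(Y, 2)
        out, _ = g.check_mahalanobis(coords, Y, S)
        assert out.status == "skipped"
        assert "singular" in out.detail


class TestPropositions:
    """Propositions: cosine = correlation and corr(z, y) = v sqrt(lam)/sqrt(s)."""

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10**6))
    def test_proposition_identities_on_random_data(self, seed):
        X = random_matrix(seed % 99991)
        Y = pb.center(X)
        S = pb.sample_covariance(Y)
        model = pb.fit_pca(Y)
        coords = pb.pc_biplot(Y, min(Y.n, Y.m))
        out_cos, _ = g.check_cosine_correlation(coords, Y, tol=1e-10)
        assert out_cos.status == "exact"
        assert g.check_feature_score_corr(model, S, tol=1e-10).status == "exact"

    def test_remark_correlations_recoverable_from_B_rows(self, ctsc_Y):
        """corr(z_k, y_j) can be recomputed purely from B's rows and sqrt(s_jj)."""
        S = pb.sample_covariance(ctsc_Y)
        model = pb.fit_pca(ctsc_Y)
        coords = pb.pc_biplot(ctsc_Y, 4)
        # b_jk / (sqrt(n-1) sqrt(s_jj)) = v_jk ell_k / (sqrt(n-1) sqrt(s_jj))
        pred = coords.B / (np.sqrt(10) * np.sqrt(np.diag(S.values))[:, None])
        for j in range(4):
            for k in range(4):
                r = np.corrcoef(model.scores[:, k], ctsc_Y.values[:, j])[0, 1]
                assert r == pytest.approx(pred[j, k], abs=1e-10)


class TestMonotoneDegradation:
    def test_gaps_shrink_to_zero_with_rank(self):
        X = random_matrix(123, n=30, m=6)
        Y = pb.center(X)
        S = pb.sample_covariance(Y)
        va, via, viia = [], [], []
        for k in range(2, 7):
            coords = pb.pc_biplot(Y, k)
            va.append(g.check_feature_sd(coords, S).max_abs_dev)
            via.append(g.check_cosine_correlation(coords, Y)[0].max_abs_dev)
            viia.append(g.check_mahalanobis(coords, Y, S)[0].max_abs_dev)
        for seq in (va, via, viia):
            assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))
            assert seq[-1] < 1e-8


class TestCorruptionDiagnostics:
    MATCHED = {
        "divisor_n": {"I.D"},
        "swap_singular": {"II.D"},
        "scale_loadings": {"VI.B"},
        "scale_B": {"V.A"},
        "permute_rows": {"VII.A"},
    }

    @pytest.mark.parametrize("mode", sorted(MATCHED))
    def test_each_mode_flips_exactly_its_check(self, mode, parts):
        Y, S, model, coords = parts
        kw = dict(Y=Y, S=S, model=model, coords=coords)
        target = pb.CORRUPTION_MODES[mode][0]
        if target == "PCAModel":
            kw["model"] = pb.corrupt(model, mode)
        elif target == "BiplotCoordinates":
            kw["coords"] = pb.corrupt(coords, mode)
        else:
            kw["Y"] = pb.corrupt(Y, mode)
        statuses = battery(**kw)
        failed = {cid for cid, s in statuses.items() if s == "fail"}
        assert failed == self.MATCHED[mode]

    def test_scale_A_breaks_coordinates_and_distance_property(self, parts):
        Y, S, model, coords = parts
        statuses = battery(Y, S, model, pb.corrupt(coords, "scale_A"))
        assert statuses["III.A"] == "fail" and statuses["VII.A"] == "fail"
        assert statuses["V.A"] == "exact" and statuses["VI.A"] == "exact"

    def test_clean_battery_all_exact(self, parts):
        assert set(battery(*parts).values()) == {"exact"}


class TestRunGrid:
    def test_fixtures_self_audit_all_exact(self, toy, ctsc):
        for fixture in (toy, ctsc):
            report = pb.run_grid(fixture.matrix)
            assert report.all_passed
            assert all(o.status == "exact" for o in report.outcomes)

    def test_rank2_gaps_annotated(self, ctsc):
        report = pb.run_grid(ctsc.matrix, rank=2)
        gaps = report.settings["rank2_gaps"]
        assert gaps["V.A"] > 0 and gaps["VI.A"] > 0 and gaps["VII.A"] > 0

    @pytest.mark.filterwarnings("ignore:m=5 > n=3")
    def test_singular_covariance_skips_mahalanobis_only(self):
        X = random_matrix(8, n=3, m=5)
        report = pb.run_grid(X)
        assert report.outcome("VII.A").status == "skipped"
        for cid in ("I.D", "II.D", "III.A", "V.A", "VI.A", "VI.B"):
            assert report.outcome(cid).status == "exact"
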