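"""PCA, NIPALS PLS, Q2 cross-validation and permutation validation."""

import numpy as np
import pytest

from pbomics.chemometrics import (
    ScalingSpec,
    fit_pca,
    fit_pls,
    permutation_validate,
    predict_left_out,
    q2_cv,
    scale_matrix,
)


class TestScaleMatrix:
    def test_pareto_equals_uv_when_sd_is_one(self):
        X = np.array([[1.0], [2.0], [3.0]])
        scaled, _, _, _ = scale_matrix(X, ScalingSpec(center=True, mode="pareto"))
        assert np.allclose(scaled.ravel(), [-1, 0, 1])

    def test_unit_variance_direct_arithmetic(self):
        X = np.array([[2.0], [4.0], [6.0]])  # SD = 2
        scaled, centers, scales, _ = scale_matrix(
            X, ScalingSpec(center=True, mode="unit_variance")
        )
        assert np.allclose(scaled.ravel(), [-1, 0, 1])
        assert centers[0] == 4.0 and scales[0] == 2.0

    def test_zero_variance_column_dropped(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        scaled, _, _, dropped = scale_matrix(
            X, ScalingSpec(center=True, mode="unit_variance")
        )
        assert scaled.shape[1] == 1
        assert list(dropped) == [1]

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            scale_matrix(np.ones((3, 2)), ScalingSpec(center=True, mode="pareto"))


class TestPCA:
    def test_rank_one_first_component_explains_all(self):
        u = np.arange(1.0, 6.0)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        with pytest.warns(UserWarning):
            res = fit_pca(u @ v, 3)
        assert res.r2x[0] == pytest.approx(1.0)

    def test_axis_aligned_data_recovers_axes(self):
        X = np.diag([3.0, 1.0]) @ np.array([[1, 0], [0, 1]], dtype=float)
        X = np.vstack([X, -X])  # centered, orthogonal design
        res = fit_pca(X, 2)
        assert np.allclose(np.abs(res.loadings), np.eye(2), atol=1e-12)

    def test_reconstruction_matches_truncated_svd(self, rng):
        X = rng.normal(size=(10, 6))
        X -= X.mean(axis=0)
        res = fit_pca(X, 3)
        recon = res.scores @ res.loadings.T
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        svd_recon = U[:, :3] * s[:3] @ Vt[:3]
        assert np.max(np.abs(recon - svd_recon)) < 1e-8
        # loadings orthonormal, components ordered by decreasing variance
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-10)
        assert np.all(np.diff(res.r2x) <= 1e-12)


class TestFitPLS:
    def test_perfect_predictor_r2y_one(self, rng):
        # centered orthogonal columns: one component isolates the predictor
        A = rng.normal(size=(15, 4))
        A -= A.mean(axis=0)
        X, _ = np.linalg.qr(A)  # columns orthonormal and still centered
        y = X[:, 2].copy()
        model = fit_pls(X, y, 1)
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-10)

    def test_perfect_predictor_full_rank_components(self, rng):
        # with correlated columns, R2Y reaches 1 once all components are in
        X = rng.normal(size=(15, 4))
        y = X[:, 2].copy()
        model = fit_pls(X, y, 4)
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_response_r2y_zero(self):
        X = np.kron(np.eye(3), np.ones((2, 1)))  # block design
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # orthogonal to all columns
        model = fit_pls(X, y, 1)
        assert model.r2y_cum < 1e-8  # no extractable covariance

    def test_matches_sklearn_on_scaled_inputs(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        for _ in range(10):
            X = rng.normal(size=(20, 5))
            y = X @ rng.normal(size=5) + 0.3 * rng.normal(size=20)
            Xc, yc = X - X.mean(0), y - y.mean()
            for ncomp in (1, 2, 3):
                mine = fit_pls(Xc, yc, ncomp).predict(Xc)
                ref = PLSRegression(n_components=ncomp, scale=False).fit(Xc, yc)
                assert np.max(np.abs(mine - ref.predict(Xc).ravel())) < 1e-6

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(rng.normal(size=(8, 3)), np.ones(8), 1)

    def test_scores_mutually_orthogonal(self, random_xy):
        X, y = random_xy
        model = fit_pls(X, y, 3)
        T = model.T
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_r2y_components_all_nonnegative(self, random_xy):
        X, y = random_xy
        model = fit_pls(X, y, 3)
        assert np.all(model.r2y >= -1e-12)  # cumulative R2Y non-decreasing

    def test_one_component_invariant_to_rotation(self, rng):
        """PLS1 predictions don't change when X columns are rotated."""
        X = rng.normal(size=(18, 5))
        y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=18)
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        p1 = fit_pls(X, y, 1).predict(X)
        p2 = fit_pls(X @ Q, y, 1).predict(X @ Q)
        assert np.allclose(p1, p2, atol=1e-8)


class TestQ2CV:
    def test_noise_free_linear_q2_near_one(self, rng):
        # one latent direction drives both X and y exactly
        t = rng.normal(size=21)
        X = np.outer(t, rng.normal(size=4))
        q2, _ = q2_cv(X, t, 1)
        assert q2[0] >= 0.999

    def test_noise_free_full_rank_cumulative_q2(self, rng):
        X = rng.normal(size=(21, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        _, q2_cum = q2_cv(X, y, 4)
        assert q2_cum >= 0.999

    def test_independent_y_expected_nonpositive(self):
        q2s = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = r.normal(size=(28, 5))
            y = r.normal(size=28)
            _, q2c = q2_cv(X, y, 1)
            q2s.append(q2c)
        assert np.mean(q2s) <= 0

    def test_hand_sized_fixture_matches_definitional_loop(self):
        """7 samples, 1 feature: PRESS by explicit held-out least squares."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.1, 1.9, 3.2, 3.9, 5.1, 5.8, 7.2])
        q2, _ = q2_cv(x[:, None], y, 1, n_segments=7)
        press = 0.0
        for k in range(7):  # each segment is one sample
            mask = np.arange(7) == k
            xt, yt = x[~mask], y[~mask]
            xc, yc = xt - xt.mean(), yt - yt.mean()
            b = (xc @ yc) / (xc @ xc)  # 1-feature PLS1 = simple regression
            yhat = yt.mean() + b * (x[mask] - xt.mean())
            press += float(((y[mask] - yhat) ** 2).sum())
        expected = 1.0 - press / float(((y - y.mean()) ** 2).sum())
        assert q2[0] == pytest.approx(expected, abs=1e-12)

    def test_q2_not_above_r2_on_training_fixtures(self, rng):
        for _ in range(5):
            X = rng.normal(size=(21, 5))
            y = X @ rng.normal(size=5) + rng.normal(size=21)
            model = fit_pls(X, y, 2)
            _, q2c = q2_cv(X, y, 2)
            assert q2c <= model.r2y_cum + 1e-9

    def test_scale_invariance_of_q2(self, random_xy):
        X, y = random_xy
        q2a, qca = q2_cv(X, y, 2)
        q2b, qcb = q2_cv(X, 7.5 * y, 2)
        assert np.allclose(q2a, q2b, atol=1e-10)
        assert qca == pytest.approx(qcb, abs=1e-10)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="segments"):
            q2_cv(rng.normal(size=(5, 3)), rng.normal(size=5), 1, n_segments=7)


class TestPermutationValidate:
    def test_deterministic_given_seed(self, random_xy):
        X, y = random_xy
        a = permutation_validate(X, y, 1, n_permutations=5, seed=3)
        b = permutation_validate(X, y, 1, n_permutations=5, seed=3)
        assert np.array_equal(a.permuted, b.permuted)
        assert a.real_q2 == b.real_q2

    def test_planted_link_beats_all_permutations(self, random_xy):
        X, y = random_xy
        res = permutation_validate(X, y, 1, n_permutations=50, seed=0)
        assert res.real_q2 > res.permuted[:, 2].max()

    def test_pure_noise_shows_no_separation(self):
        r = np.random.default_rng(5)
        X = r.normal(size=(28, 10))
        y = r.normal(size=28)
        res = permutation_validate(X, y, 1, n_permutations=50, seed=1)
        # real Q2 inside the permuted distribution
        assert res.real_q2 <= np.quantile(res.permuted[:, 2], 0.95)


class TestPredictLeftOut:
    def test_noise_free_predictions_exact(self, rng):
        X = rng.normal(size=(21, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        preds = predict_left_out(X, y, 3, n_folds=7, seed=0, n_repeats=2)
        assert np.max(np.abs(preds - y)) < 1e-6

    def test_folds_deterministic(self, random_xy):
        X, y = random_xy
        a = predict_left_out(X, y, 1, n_folds=5, seed=11, n_repeats=3)
        b = predict_left_out(X, y, 1, n_folds=5, seed=11, n_repeats=3)
        assert np.array_equal(a, b)

    def test_permuted_y_groups_indistinguishable(self):
        """With dose labels permuted, held-out predictions carry no dose signal."""
        from scipy import stats

        r = np.random.default_rng(2)
        dose = np.repeat([0.0, 50.0, 500.0, 1000.0], 5)
        X = r.normal(size=(20, 8)) + 0.5 * dose[:, None] / 1000.0
        yperm = r.permutation(dose)
        preds = predict_left_out(X, yperm, 1, n_folds=5, seed=4, n_repeats=5)
        mean_pred = preds.mean(axis=0)
        groups = [mean_pred[dose == d] for d in (0, 50, 500, 1000)]
        _, p = stats.f_oneway(*groups)
        assert p > 0.05
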