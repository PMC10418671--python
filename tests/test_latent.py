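"""NIPALS PCA / PLS-DA / OPLS-DA against independent oracles, VIP algebra,
cross-validated Q2 and permutation/CV-ANOVA calibration."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from omniblock.data import ValidationError
from omniblock.latent import (
    choose_components,
    compute_vip,
    cross_validate,
    cv_anova,
    encode_binary,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    permutation_test,
)


def _centered(rng, n, p):
    X = rng.standard_normal((n, p))
    return X - X.mean(axis=0)


def _labels(n):
    return np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))


class TestPCA:
    def test_rank_one_single_component(self, rng):
        u = rng.standard_normal(20)
        v = rng.standard_normal(6)
        X = np.outer(u, v)
        X -= X.mean(axis=0)
        m = fit_pca(X, 1)
        assert m.r2x >= 1 - 1e-10

    def test_matches_eigendecomposition(self, rng):
        X = _centered(rng, 30, 8)
        m = fit_pca(X, 4)
        w, v = np.linalg.eigh(X.T @ X)
        order = np.argsort(-w)
        for a in range(4):
            pv = v[:, order[a]]
            err = min(
                np.abs(m.loadings[:, a] - pv).max(),
                np.abs(m.loadings[:, a] + pv).max(),
            )
            assert err < 1e-8
        # scores are X projected on loadings
        np.testing.assert_allclose(m.scores, X @ m.loadings, atol=1e-8)

    def test_missing_values_recover_subspace(self, rng):
        U = rng.standard_normal((60, 2))
        V = rng.standard_normal((2, 20))
        X = U @ V + 0.01 * rng.standard_normal((60, 20))
        X -= X.mean(axis=0)
        truth = np.linalg.svd(X)[2][:2].T
        Xm = np.where(rng.random(X.shape) < 0.05, np.nan, X)
        m = fit_pca(Xm, 2)
        angle = np.degrees(subspace_angles(m.loadings, truth)).max()
        assert angle < 2.0

    def test_sign_convention(self, rng):
        X = _centered(rng, 25, 5)
        m = fit_pca(X, 2)
        for a in range(2):
            assert m.loadings[np.argmax(np.abs(m.loadings[:, a])), a] > 0

    def test_component_bound(self, rng):
        with pytest.raises(ValidationError):
            fit_pca(_centered(rng, 5, 3), 3)


class TestPLSDA:
    def test_constructed_signal_r2y(self, rng):
        n = 40
        y = _labels(n)
        yc, _ = encode_binary(y)
        X = np.c_[yc, 0.01 * _centered(rng, n, 5)]
        m = fit_plsda(X, y, A=1)
        assert m.r2y > 0.99

    def test_full_rank_equals_ols(self, rng):
        n, p = 40, 5
        X = _centered(rng, n, p)
        y = _labels(n)
        rng.shuffle(y)
        yc, _ = encode_binary(y)
        m = fit_plsda(X, y, A=p)
        yhat_pls = m.scores @ m.y_loadings
        b = np.linalg.lstsq(X, yc, rcond=None)[0]
        np.testing.assert_allclose(yhat_pls, X @ b, atol=1e-8)
        np.testing.assert_allclose(X @ m.coefficients, X @ b, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = _centered(rng, 10, 3)
        with pytest.raises(ValidationError):
            fit_plsda(X, np.array(["a"] * 10), 1)

    def test_deflation_norm_identity(self, rng):
        X = _centered(rng, 25, 8)
        y = _labels(25)
        rng.shuffle(y)
        m = fit_plsda(X, y, A=3)
        # ||X||^2 = sum_a ||t_a p_a'||^2 + ||residual||^2
        total = np.sum(X**2)
        expl = sum(
            np.sum(np.outer(m.scores[:, a], m.loadings[:, a]) ** 2) for a in range(3)
        )
        resid = X.copy()
        for a in range(3):
            resid -= np.outer(m.scores[:, a], m.loadings[:, a])
        assert abs(total - (expl + np.sum(resid**2))) / total < 1e-8

    def test_scores_mutually_orthogonal(self, rng):
        X = _centered(rng, 30, 10)
        y = _labels(30)
        rng.shuffle(y)
        m = fit_plsda(X, y, A=4)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()


class TestOPLSDA:
    def test_zero_orthogonal_reduces_to_plsda(self, rng):
        X = _centered(rng, 30, 6)
        y = _labels(30)
        rng.shuffle(y)
        m0 = fit_oplsda(X, y, n_orthogonal=0)
        m1 = fit_plsda(X, y, A=1)
        np.testing.assert_allclose(m0.scores[:, 0], m1.scores[:, 0], atol=1e-10)

    def test_structured_noise_removed(self, rng):
        n = 80
        y = _labels(n)
        yc, _ = encode_binary(y)
        orth = rng.standard_normal(n)
        orth -= orth @ yc / (yc @ yc) * yc
        X = np.outer(yc, np.ones(5)) + 6 * np.outer(orth, rng.standard_normal(5))
        X += 0.3 * rng.standard_normal((n, 5))
        X -= X.mean(axis=0)
        t_pls = fit_plsda(X, y, 1).scores[:, 0]
        t_opls = fit_oplsda(X, y, 1).scores[:, 0]
        corr = lambda t: abs(np.corrcoef(t, yc)[0, 1])
        assert corr(t_opls) > corr(t_pls)

    def test_predictive_orthogonal_to_orthogonal_scores(self, rng):
        X = _centered(rng, 40, 10)
        y = _labels(40)
        rng.shuffle(y)
        m = fit_oplsda(X, y, n_orthogonal=3)
        dots = np.abs(m.ortho_scores.T @ m.scores[:, 0])
        assert dots.max() < 1e-8

    def test_too_many_orthogonal(self, rng):
        X = _centered(rng, 8, 4)
        with pytest.raises(ValidationError):
            fit_oplsda(X, _labels(8), n_orthogonal=4)


class TestVIP:
    def test_two_feature_example(self):
        # A=1, weights (1, 0), p=2 -> VIPs (sqrt(2), 0)
        y = np.array(["a", "a", "b", "b", "a", "b"])
        yc, _ = encode_binary(y)
        X = np.c_[yc, np.zeros(6)]
        X[:, 1] = 1e-12 * np.array([1, -1, 1, -1, 1, -1])
        m = fit_plsda(X - X.mean(0), y, A=1)
        vip = compute_vip(m)
        assert vip[0] == pytest.approx(np.sqrt(2), abs=1e-6)
        assert vip[1] == pytest.approx(0.0, abs=1e-6)

    def test_equal_weights_all_one(self):
        y = np.array(["a", "a", "a", "b", "b", "b"])
        yc, _ = encode_binary(y)
        X = np.tile(yc[:, None], (1, 4)).astype(float)
        X += 1e-9
        m = fit_plsda(X - X.mean(0), y, A=1)
        np.testing.assert_allclose(compute_vip(m), 1.0, atol=1e-6)

    def test_mean_square_one_identity(self, rng):
        for p, A in [(10, 1), (10, 3), (25, 5)]:
            X = _centered(rng, 40, p)
            y = _labels(40)
            rng.shuffle(y)
            m = fit_plsda(X, y, A=A)
            assert abs(np.mean(compute_vip(m) ** 2) - 1) < 1e-10
        mo = fit_oplsda(X, y, 2)
        assert abs(np.mean(compute_vip(mo) ** 2) - 1) < 1e-10

    def test_pca_rejected(self, rng):
        m = fit_pca(_centered(rng, 10, 4), 2)
        with pytest.raises(ValidationError):
            compute_vip(m)


class TestCrossValidation:
    def test_deterministic_given_seed(self, rng):
        X = _centered(rng, 40, 10)
        y = _labels(40)
        rng.shuffle(y)
        r1 = cross_validate(X, y, 2, seed=5)
        r2 = cross_validate(X, y, 2, seed=5)
        assert r1.q2 == r2.q2

    def test_perfect_separation_high_q2(self, rng):
        y = _labels(60)
        yc, _ = encode_binary(y)
        X = np.c_[yc + 0.05 * rng.standard_normal(60), 0.1 * _centered(rng, 60, 5)]
        res = cross_validate(X, y, 1, seed=0)
        assert res.q2 > 0.9

    def test_q2_at_most_r2y(self, rng):
        X = _centered(rng, 50, 15)
        y = _labels(50)
        rng.shuffle(y)
        m = fit_plsda(X, y, A=2)
        res = cross_validate(X, y, 2, seed=1)
        assert res.q2 <= m.r2y

    def test_null_labels_nonpositive_q2_rate(self):
        neg = 0
        for s in range(30):
            r = np.random.default_rng(1000 + s)
            X = r.standard_normal((100, 20))
            y = _labels(100)
            r.shuffle(y)
            neg += cross_validate(X, y, 2, n_folds=7, seed=s).q2 <= 0
        assert neg >= 27  # >= 90% of seeds


class TestPermutationAndCvAnova:
    def test_minimum_p_bound(self, rng):
        # strong real signal: observed Q2 beats every permutation
        y = _labels(30)
        yc, _ = encode_binary(y)
        X = np.c_[yc, 0.05 * _centered(rng, 30, 4)]
        res = permutation_test(X, y, 1, n_permutations=200, seed=0, n_folds=5)
        assert res.perm_p == pytest.approx(1 / 201)
        assert len(res.perm_q2) == 200

    def test_identity_permutation_counts_in_numerator(self, rng):
        X = _centered(rng, 20, 5)
        y = _labels(20)
        res = permutation_test(X, y, 1, n_permutations=30, seed=2, n_folds=4)
        count = int(np.sum(res.perm_q2 >= res.q2))
        assert res.perm_p == pytest.approx((1 + count) / 31)
        assert res.perm_p >= 1 / 31

    def test_cv_anova_trivial_cases(self):
        res = cross_validate(np.random.default_rng(0).standard_normal((20, 4)),
                             _labels(20), 1, n_folds=4, seed=0)
        res.press = res.ss_tot
        f, df1, df2, p = cv_anova(res)
        assert f == 0.0 and p == 1.0
        res.press = res.ss_tot / 1e6
        f2, *_, p2 = cv_anova(res)
        assert f2 > 0 and p2 < 1e-10

    def test_cv_anova_matches_recomputation(self, rng):
        y = _labels(40)
        yc, _ = encode_binary(y)
        X = np.c_[yc + 0.3 * rng.standard_normal(40), _centered(rng, 40, 6)]
        res = cross_validate(X, y, 2, seed=3)
        f, df1, df2, p = cv_anova(res)
        f_manual = ((res.ss_tot - res.press) / 2) / (res.press / (40 - 2 - 1))
        assert f == pytest.approx(f_manual)
        assert df1 == 2 and df2 == 37

    def test_cv_anova_df_guard(self):
        res = cross_validate(np.random.default_rng(0).standard_normal((6, 3)),
                             _labels(6), 1, n_folds=3, seed=0)
        res.n = 2
        with pytest.raises(ValidationError):
            cv_anova(res)


def test_choose_components_prefers_informative_rank(rng):
    y = _labels(60)
    yc, _ = encode_binary(y)
    X = np.c_[yc + 0.1 * rng.standard_normal(60), _centered(rng, 60, 10)]
    A = choose_components(X, y, max_A=5, seed=0)
    assert 1 <= A <= 5
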